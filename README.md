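# prfscan

Prediction of programmed ribosomal frameshift (PRF) sites in annotated
prokaryotic and viral genomes.

During a PRF, the translating ribosome pauses on a *slippery sequence* and
slips one nucleotide backward (−1) or forward (+1), so translation
continues in an alternate frame past the original stop codon and produces
a fusion protein — the mechanism behind, e.g., phage tail assembly
chaperone genes and the SARS-CoV-2 polyprotein. In GenBank annotations
these genes appear as CDS features with a compound `join(...)` location
spanning two frames. `prfscan` is for genome annotators and phage/virus
researchers who want these sites detected automatically instead of by
manual curation.

## Method

For every pair of consecutive same-strand genes (A, B) in different
frames, the *overlap window* is the stop-free stretch in B's frame bounded
5' by the nearest upstream stop (and A's start) and 3' by A's in-frame
stop codon — the only region where a shift could fuse A and B. Every
in-frame codon boundary in the window is tested against ten slippery-motif
run patterns (eight backward, e.g. the canonical heptamer X&nbsp;X&nbsp;X&nbsp;Y&nbsp;Y&nbsp;Y&nbsp;Z as
`threethree`; two forward, gated by A1 &gt; A0 codon abundance). Each
candidate site, modelled with the motif occupying the ribosomal E- and
P-sites and the A-site empty, gets an 11-value feature vector:

| feature | meaning | range |
|---|---|---|
| DIR | shift direction | −1, +1 |
| RBS1 | 28-bin Shine-Dalgarno score upstream of the P-site | 0–27 |
| RBS2 | frequency-based SD score | 0.0–6.3 |
| MOTIF | slippery motif class id | 0–9 |
| A0, A1 | genome-wide usage of the in-frame / shifted A-site codon | 0–1 |
| LF50, LF100, HK50, HK100 | normalised MFE of the 50/100 bp windows at offset 3, two folding slots | 0–1 |
| N | distance to the +0 in-frame stop codon | ≥ 0 nt |

MFE values are normalised as `|MFE| / length / GC`, clamped to [0, 1]. A
histogram gradient-boosting classifier (L2 = 1.0, early stopping off, so
runs are deterministic) assigns each site to {−1, 0, +1}; per overlap
region only the highest-scoring non-zero candidate is reported. Training
labels come from `join` annotations: two fragments ≤ 10 bp apart mark a
frameshift, and candidate motifs further than 10 bp from the annotated
shift count as negatives. Leave-one-group-out validation supports GENOME,
MASH95 (MinHash clustering at distance 0.05, k = 16, sketch size 400), and
externally supplied CLUSTER/SUBCLUSTER groupings.

## Worked example

`examples/train_and_predict.py` trains on a 12-genome synthetic corpus
(planted frameshift genes provide the `join` labels) and predicts on an
unseen genome:

```
trained on 65 candidates, 16 of them labelled as shifts

query genome synth4242: planted threethree (backward) on strand 1
predicted: direction -1, motif threethree, P(shift) = 0.973, N = 24 nt
  implied joined gene: join(1190..1254,1255..1329) strand +1
```

The classifier recovers the planted backward shift: direction −1 at the
planted slippery site with probability 0.973, and the implied `join`
coordinates place the fragment boundary at the annotation convention
(abutting fragments for a −1 shift). `examples/scan_planted_genome.py`
shows the candidate table itself — the true site stands out through its
RBS1 = 27 Shine-Dalgarno element and small N — and
`examples/cluster_by_identity.py` demonstrates the ~95%-identity MinHash
grouping used for leakage-controlled validation.

The same pipeline is scriptable from the shell:

```bash
prfscan fixtures --out corpus --seed 5          # synthetic corpus + truth
prfscan train corpus/*.gbk --out model.joblib
prfscan predict genome.gbk --model model.joblib # TSV of calls
prfscan validate corpus/*.gbk --level GENOME    # confusion summary
```

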