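# Methods

## Model

A programmed ribosomal frameshift (PRF) is modelled as a classification
problem over candidate *slippery sites*. A candidate exists wherever a
slippery-motif run pattern ends on a codon boundary of the upstream gene's
frame inside an *overlap window* — the region where a shift could fuse two
consecutive same-strand genes annotated in different frames. The window is
bounded 3' by the upstream gene's +0 in-frame stop codon, and 5' by the
nearest stop upstream of the downstream gene in that gene's frame, further
clamped at the upstream gene's start (a ribosome cannot shift before it
has begun translating the gene). The site is modelled with the motif
occupying the ribosomal E- and P-sites and the A-site codon empty,
awaiting tRNA recruitment.

Coordinates are 0-based half-open everywhere except the GenBank boundary
(`genbank_io`), which is the single adapter between the flat file's
1-based inclusive convention and the internal one. All per-strand analysis
runs on a strand-oriented *view* (reverse-strand genes are analysed on the
reverse complement), so frames are always `start % 3` and windows always
extend rightward.

### Slippery motifs

Ten run patterns are catalogued as package data (`data/motifs.tsv`): eight
backward (six, threethree, fivetwo, twofive, twofour, threetwotwo, five,
twoonefour) and two forward (four, three). A pattern `[p1..pk]` matches
when the bases immediately 5' of the A-site split into runs of exactly
those lengths with adjacent runs differing; the 5'-most run may extend
further 5' (maximal-run surplus). When several patterns match, precedence
goes to the pattern least likely by chance: longer total length first,
then fewer runs (a single 6-run is 4-fold rarer than a 3+3). Forward
motifs are additionally gated on A1 > A0 — the shifted A-site codon must
be more abundant genome-wide than the in-frame one — because 3/4-base runs
are too frequent to be informative alone.

### Features and their defaults

* **DIR** — motif direction, −1 or +1.
* **RBS1** (0–27) and **RBS2** (0.0–6.3) — Shine-Dalgarno scores upstream
  of the P-site codon. Spacers are measured from the motif 3' end to the
  P-site codon start: 3–15 nt for the 28-bin scorer, 3–12 nt (ten sizes)
  for the frequency scorer. Both tables ship as TSV package data with
  their construction documented in `data/PROVENANCE.md`; the frequency
  score is `log2(frequency / background)` clipped to [0, 6.3]. The SD
  spacing transplants start-codon RBS conventions to the slippery site;
  the distance convention is config-exposed because no single standard
  exists for internal sites.
* **A0 / A1** — relative genome-wide usage of the in-frame and shifted
  A-site codons, counted over every annotated CDS (joined features over
  their fragment-concatenated frame). All 64 codons count equally, so stop
  codons appear as one-per-gene rare codons — intentional, since pausing
  on a stop can also trigger a shift. For backward sites A1 is the codon
  one base 5' of the A-site (the −1-frame codon occupying the A-site
  position); the alternative "next codon translated in −1 frame" reading
  is noted as a convention risk.
* **LF50/LF100/HK50/HK100** — normalised minimum free energy of the 50 and
  100 bp windows starting at offset 3 (immediately after the three A-site
  bases), for two configurable folding slots. Normalisation is
  `clamp(|mfe| / length / GC, 0, 1)` with GC as a fraction (this matches
  the documented 0–1 feature range; dividing by GC percent would not).
  Truncated windows are folded and normalised at actual length.
* **N** — nucleotides from the A-site codon start to the first base of the
  +0 in-frame stop codon; stop-adjacent sites give small values (15 for a
  site five codons from the stop). N separates plausible sites near the
  stop from chance motifs far upstream.

### Folding backends

Dedicated hairpin (LinearFold-class) and pseudoknot (HotKnots-class)
engines are deliberately not reimplemented; the two window slots accept
any backend honouring the contract *deterministic, mfe ≤ 0, structure
length = window length*. The built-in `baseline_nested` backend is a
Nussinov-style dynamic program over nested pairings with pair energies
GC −3, AU −2, GU −1 and minimum hairpin loop 3, summed over pairs; it is
exact (verified against exhaustive enumeration of all nested pairings for
windows ≤ 14 nt). An `rnafold` adapter shells out to ViennaRNA's RNAfold
when it is on PATH.

Known limitation: a pair-sum folder with no stacking or loop penalties
pairs random sequence almost as well as designed hairpins, so with the
default backend the GC-normalised feature saturates near 1.0 on GC-rich
coding windows and carries little contrast; classification then leans on
the RBS, N, motif, and codon-usage features. A thermodynamic backend
(RNAfold) restores the dynamic range, and tests assert the
planted-hairpin-versus-background contrast strictly only under such a
backend.

### Classifier

`HistGradientBoostingClassifier` with library defaults except
`l2_regularization=1.0` and `early_stopping=False` (training and
prediction are then deterministic for fixed inputs; `random_state` is
pinned to 0). Classes are {−1, 0, +1}. Class imbalance is left to the
trees, matching the default-parameters design. Per overlap region, the
candidate with the largest non-zero-class probability whose argmax class
is non-zero becomes the region's single call ("highest-scoring site");
thresholding on that probability is config-exposed but off by default.
Persisted models carry the feature-column order and motif-id table to
prevent silent schema drift.

### Labels and evaluation

Joined CDS features with exactly two fragments ≤ 10 bp apart are treated
as annotated frameshifts (abutting fragments = backward, one skipped base
= forward; other separations are classified by the fragment frame
difference modulo 3). Wider separations, more fragments, or fragments
wrapping a circular genome's origin are inteins/introns/wrap artefacts and
are excluded. For training, joined genes are split into pseudo gene pairs
and candidate motifs within 10 bp of the annotated boundary take the
shift's direction as label; everything else is 0. Validation is
leave-one-group-out at GENOME (each genome its own group), MASH95
(single-linkage MinHash clusters at distance ≤ 0.05, k = 16, sketch size
400, splitmix64 hash with a fixed seed), or externally supplied
CLUSTER/SUBCLUSTER labels. A region whose pair came from a joined gene
counts TP when the merged prediction lands within 10 bp of the
annotation, FN otherwise (a wrong-location call also counts FP); negative
regions count FP/TN.

## Synthetic data

The generator (`fixtures`) emulates the statistical structure the method
assumes rather than any particular organism: per-genome codon usage drawn
from a Dirichlet(2) over the 61 sense codons (so the A1 > A0 gate can be
exercised both ways), background at 60% GC (phage-like), ordinary genes of
30–80 codons on random strands, and two cassettes:

* a **planted PRF gene** — a joined CDS whose fragments meet at a chosen
  motif on a codon boundary, with an AGGAGG element at 7 nt spacer, a GC
  inverted-repeat hairpin (stem 8 bp) at offset 3, the +0 stop at
  N = 24 nt (near the ~26 nt seen in phage chaperone shifts), and
  fragment separation 0 or 1 by direction;
* a **decoy pair** — two separate overlapping genes with a chance
  threethree motif but no SD element, no hairpin, and N = 60 nt, providing
  hard negatives.

Guard bases around the motif stop its runs bleeding into neighbouring
sequence and changing class; junction codons are rejection-sampled so the
geneB frame stays stop-free exactly where the scanner requires it. The
generator is deterministic per seed, and every planted site is recoverable
by the scanner (generator–scanner closure is enforced in tests for all ten
motif classes on both strands).

What the generator does *not* emulate: sequence homology between related
genomes (corpus "families" are label groupings, not sequence families),
misannotation noise, pseudoknots, G:U-aware motif constraints, and
tRNA-pool effects. Passing tests therefore show the pipeline recovers the
signal model it targets, not that real-genome recall will match the
synthetic numbers.

## Problem sizes and numerics

The end-to-end recovery experiment uses a 60-genome corpus (40 backward
across all eight motif classes, 10 forward, 10 without a PRF) under
5-group leave-one-group-out, plus 30-genome corpora over five seeds for
the GENOME-versus-coarse recall trend; featurization dominates runtime and
these sizes keep the whole suite comfortably interactive. Folding uses an
O(n²)-space integer DP with exact traceback (integer energies make
tie-breaking deterministic: unpaired-right is preferred, then pairing,
then the first split point). Windows off the contig score 0.0 with a
warning; empty genomes and single-class training sets raise. The MinHash
hash is splitmix64 over 2-bit canonical k-mer codes with a fixed seed, so
sketches, distances, and validation splits are machine-independent.

## Design choices made where the design was open

* Reverse-strand joined genes are stored and split in biological 5'→3'
  fragment order.
* "Consecutive" genes means adjacent on the same strand in coordinate
  order; opposite-strand genes in between do not break adjacency, and
  genes wholly contained in another gene are skipped.
* Any pair whose stop-free window reaches into geneA is accepted; no
  minimum overlap between the genes themselves is required.
* The motif-class integer coding (MOTIF 0–9) is an arbitrary fixed
  bijection shipped in the catalog; tree models are insensitive to it.
* Inter-run inequality is required between adjacent runs only.
* The join-separation threshold (10 bp), fragment count (2), label radius
  (10 bp), fold windows (50/100) and offset (3) are config constants with
  the stated defaults.
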