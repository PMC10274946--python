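# Package data provenance

All three tables are authored by this package and frozen to TSV by
`scripts/make_rbs_tables.py` (RBS tables) or by hand (motif catalog); none
is copied from another program's distribution.

## motifs.tsv
The ten slippery-sequence run patterns, their fixed integer ids (the MOTIF
feature), shift direction, and precedence rank. Precedence orders patterns
by decreasing length and then by fewer runs, i.e. by decreasing rarity
under a uniform base model, so that a sequence matching several nested
patterns is reported as the most specific one.

## rbs_prodigal_bins.tsv
A Prodigal-style 28-bin ribosome-binding-site table: bin 0 means no motif;
bins 1-27 cover the nine exact Shine-Dalgarno submotifs of AGGAGG
(GGA, GAG, AGG, AGGA, GGAG, GAGG, AGGAG, GGAGG, AGGAGG) crossed with three
spacer classes (11-15, 3-4, 5-10 nt between the motif 3' end and the
P-site codon). The ranking is motif strength first, spacer second, with
5-10 nt the optimal spacing; AGGAGG at 5-10 nt is bin 27. This follows
the 28-bin *concept* of the Prodigal gene caller but the bin ordering is
this package's own construction.

## rbs_rast_frequencies.tsv
A RAST-style observed-frequency table: 191 motifs x 10 spacer sizes
(3-12 nt). The motif set is the 191 highest-scoring 3-6-mers under an
ungapped similarity to the extended anti-SD complement AAGGAGGTGA
(+2 match / -3 mismatch; ties broken by longer motif, then lexicographic).
Frequencies are synthetic, generated so that
`log2(frequency / background)` - with background `0.25^len * 0.1` - equals
`6.3 * motif_quality * spacer_quality`, peaking at 6.3 for AGGAGG with a
6-8 nt spacer. The derived score therefore spans the documented 0.0-6.3
range.
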