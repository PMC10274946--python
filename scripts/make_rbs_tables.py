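"""Regenerate the ribosome-binding-site scoring tables shipped as package data.

Both tables are this package's own constructions (documented in
src/prfscan/data/PROVENANCE.md); this script exists so the frozen TSVs are
auditable and reproducible.  Run from the repository root:

    python scripts/make_rbs_tables.py
"""

from __future__ import annotations

import pathlib

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "prfscan" / "data"

# ---------------------------------------------------------------- 28-bin table
# Exact Shine-Dalgarno submotifs of AGGAGG, weakest to strongest.
BIN_MOTIFS = ["GGA", "GAG", "AGG", "AGGA", "GGAG", "GAGG",
              "AGGAG", "GGAGG", "AGGAGG"]
# Spacer classes (nt from motif 3' end to the P-site codon), worst to best.
BIN_SPACERS = ["11-15", "3-4", "5-10"]


def write_bin_table() -> None:
    lines = ["# Prodigal-style 28-bin RBS table: bin 0 is the no-motif",
             "# default; bins 1-27 rank motif strength first, spacer second.",
             "motif\tspacer\tbin"]
    for mi, motif in enumerate(BIN_MOTIFS):
        for si, spacer in enumerate(BIN_SPACERS):
            lines.append(f"{motif}\t{spacer}\t{mi * 3 + si + 1}")
    (DATA / "rbs_prodigal_bins.tsv").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------- frequency table
TEMPLATE = "AAGGAGGTGA"          # extended anti-SD complement region
MATCH, MISMATCH = 2, -3
SPACER_SIZES = range(3, 13)      # 10 spacer sizes
SPACER_QUALITY = {3: 0.5, 4: 0.6, 5: 0.8, 6: 1.0, 7: 1.0, 8: 1.0,
                  9: 0.8, 10: 0.7, 11: 0.6, 12: 0.5}
N_MOTIFS = 191
MAX_SCORE = 6.3
SPACER_BACKGROUND = 1.0 / len(SPACER_SIZES)


def background(motif: str) -> float:
    return 0.25 ** len(motif) * SPACER_BACKGROUND


def similarity(motif: str) -> int:
    best = MISMATCH * len(motif)
    for off in range(len(TEMPLATE) - len(motif) + 1):
        s = sum(MATCH if motif[i] == TEMPLATE[off + i] else MISMATCH
                for i in range(len(motif)))
        best = max(best, s)
    return best


def all_kmers(k: int):
    if k == 0:
        yield ""
        return
    for rest in all_kmers(k - 1):
        for base in "ACGT":
            yield rest + base


def write_frequency_table() -> None:
    scored = []
    for k in range(3, 7):
        for m in all_kmers(k):
            scored.append((-similarity(m), -len(m), m))
    scored.sort()
    motifs = [m for _, _, m in scored[:N_MOTIFS]]
    max_sim = -scored[0][0]
    lines = ["# SD-motif observed-frequency table: 191 motifs x 10 spacer",
             "# sizes; score = log2(frequency / background) clipped to",
             "# [0, 6.3] (see PROVENANCE.md).",
             "motif\tspacer\tfrequency"]
    for m in motifs:
        qm = max(similarity(m), 0) / max_sim
        for s in SPACER_SIZES:
            target = MAX_SCORE * qm * SPACER_QUALITY[s]
            freq = background(m) * 2.0 ** target
            lines.append(f"{m}\t{s}\t{freq:.6e}")
    (DATA / "rbs_rast_frequencies.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    write_bin_table()
    write_frequency_table()
    print("wrote", DATA / "rbs_prodigal_bins.tsv")
    print("wrote", DATA / "rbs_rast_frequencies.tsv")
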