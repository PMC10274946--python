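"""Shine-Dalgarno ribosome-binding-site scoring upstream of the P-site.

An SD-like element a few bases 5' of the slippery site can pair with the
16S rRNA anti-SD near the ribosome's mRNA entrance channel and stall the
ribosome — one of the signals that promotes frameshifting.  Two scorers
quantify this, both pure functions of the upstream context:

``score_rbs_prodigal``
    a 28-bin integer score (0 = no motif, 27 = AGGAGG at optimal spacing),
    in the style of the Prodigal gene caller's RBS bins;
``score_rbs_rast``
    a real-valued score in [0, 6.3] derived from an observed-frequency
    table of 191 SD motifs at 10 spacer sizes, in the style of the RAST
    annotation server.

Both tables ship as package data (see ``data/PROVENANCE.md``).  The spacer
is measured from the motif's 3' end to the first base of the P-site codon;
spacers of 3-15 nt (bins) and 3-12 nt (frequencies) are searched, matching
SD spacing conventions for start codons transplanted to the slippery site.
"""

from __future__ import annotations

import math
from functools import lru_cache
from importlib import resources

from .candidates import GenomeView
from .genbank_io import GenomeRecord

__all__ = [
    "score_rbs_prodigal",
    "score_rbs_rast",
    "RBS_MAX_BIN",
    "RBS_MAX_SCORE",
]

RBS_MAX_BIN = 27
RBS_MAX_SCORE = 6.3
_BIN_SPACER_RANGE = range(3, 16)      # nt, inclusive of 3..15
_FREQ_SPACER_RANGE = range(3, 13)     # the 10 tabulated spacer sizes
_SPACER_BACKGROUND = 0.1


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("prfscan.data").joinpath(name).read_text()
    return [line.split("\t") for line in text.splitlines()
            if line.strip() and not line.startswith("#")
            and not line.startswith("motif\t")]


@lru_cache(maxsize=1)
def _bin_table() -> dict[tuple[str, int], int]:
    """(motif, spacer nt) -> bin, expanded from the spacer-class table."""
    table: dict[tuple[str, int], int] = {}
    for motif, spacer_class, bin_ in _read_table("rbs_prodigal_bins.tsv"):
        lo, hi = (int(x) for x in spacer_class.split("-"))
        for s in range(lo, hi + 1):
            table[(motif, s)] = int(bin_)
    return table


@lru_cache(maxsize=1)
def _freq_table() -> dict[tuple[str, int], float]:
    return {(motif, int(spacer)): float(freq)
            for motif, spacer, freq in _read_table("rbs_rast_frequencies.tsv")}


def _upstream_seq(genome, p_site_pos: int, strand: int) -> tuple[str, int]:
    """Sequence context and the view position of the P-site codon start."""
    if isinstance(genome, GenomeRecord):
        view = GenomeView(genome, strand)
        return view.seq, p_site_pos
    return str(genome), p_site_pos


def score_rbs_prodigal(genome, p_site_pos: int, strand: int = 1) -> int:
    """Best RBS bin (0-27) for the context upstream of the P-site codon.

    ``genome`` may be a GenomeRecord (``p_site_pos`` on the given strand's
    view) or a plain sequence string.  Returns 0 when no tabulated motif
    sits at a tabulated spacer; windows truncated by the contig edge are
    scored on the available bases.
    """
    seq, p = _upstream_seq(genome, p_site_pos, strand)
    table = _bin_table()
    best = 0
    for (motif, spacer), bin_ in table.items():
        start = p - spacer - len(motif)
        if start < 0:
            continue
        if seq[start:start + len(motif)] == motif:
            best = max(best, bin_)
    return best


def score_rbs_rast(genome, p_site_pos: int, strand: int = 1) -> float:
    """Best frequency-derived RBS score in [0, 6.3] upstream of the P-site."""
    seq, p = _upstream_seq(genome, p_site_pos, strand)
    table = _freq_table()
    best = 0.0
    for spacer in _FREQ_SPACER_RANGE:
        for length in (3, 4, 5, 6):
            start = p - spacer - length
            if start < 0:
                continue
            freq = table.get((seq[start:start + length], spacer))
            if freq is None:
                continue
            background = 0.25 ** length * _SPACER_BACKGROUND
            score = math.log2(freq / background)
            best = max(best, min(max(score, 0.0), RBS_MAX_SCORE))
    return best
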