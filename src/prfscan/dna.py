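"""Small nucleotide-sequence helpers shared across the package.

All downstream computation uses 0-based half-open coordinates on an
uppercase A/C/G/T/N alphabet; :mod:`prfscan.genbank_io` is the only
boundary where 1-based inclusive GenBank coordinates appear.
"""

from __future__ import annotations

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def clean_sequence(seq: str) -> str:
    """Uppercase, map U->T, and collapse non-ACGT characters to N."""
    s = seq.upper().replace("U", "T")
    return "".join(c if c in "ACGT" else "N" for c in s)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over the full window length (N counts in the denominator)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
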