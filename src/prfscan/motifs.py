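"""Slippery-sequence motif detection inside overlap regions.

A slippery site is described by the run structure of the bases occupying
the ribosome's E- and P-sites (and, for 7-nt motifs, one base 5' of them),
with the A-site codon empty and waiting.  Eight run patterns mark backward
(-1) shifts and two mark forward (+1) shifts; the forward ones are only
reported when the shifted A-site codon is more abundant genome-wide than
the in-frame one (the A1 > A0 gate), because 3- and 4-base runs are too
common to be informative on their own.

Matching semantics: a pattern ``[p1, .., pk]`` (5'->3') matches the window
immediately 5' of a codon boundary when its last ``sum(p)`` bases split
into runs of those exact lengths, adjacent runs holding different
nucleotides; the 5'-most run may extend further 5' (maximal-run surplus is
ignored).  When several patterns match, the one with the lower chance of
occurring at random takes precedence: longer patterns first, then fewer
runs.  The catalog ships as package data so the patterns are editable
without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

from .candidates import OverlapRegion

__all__ = [
    "MotifClass",
    "SlipperyCandidate",
    "load_catalog",
    "match_motif",
    "scan_region",
    "label_candidates",
    "LABEL_RADIUS",
    "MOTIF_WINDOW",
]

# Candidates further than this many bases from an annotated shift are
# treated as chance motif occurrences (negative cases).
LABEL_RADIUS = 10
# Longest catalogued pattern; the matcher looks at most this far 5'.
MOTIF_WINDOW = 7


@dataclass(frozen=True)
class MotifClass:
    name: str
    motif_id: int
    direction: int            # -1 backward, +1 forward
    runs: tuple[int, ...]     # 5'->3' run lengths
    precedence: int           # 1 = highest

    @property
    def length(self) -> int:
        return sum(self.runs)


@dataclass(frozen=True)
class SlipperyCandidate:
    region: OverlapRegion
    a_site_pos: int           # view position of the empty A-site codon start
    motif: MotifClass
    motif_span: tuple[int, int]
    direction: int


@lru_cache(maxsize=1)
def load_catalog() -> tuple[MotifClass, ...]:
    """The ten motif classes, sorted by precedence (highest first)."""
    text = resources.files("prfscan.data").joinpath("motifs.tsv").read_text()
    classes = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, mid, direction, runs, prec = line.split("\t")
        classes.append(MotifClass(
            name=name, motif_id=int(mid), direction=int(direction),
            runs=tuple(int(r) for r in runs.split(",")),
            precedence=int(prec)))
    classes.sort(key=lambda m: m.precedence)
    if len(classes) != 10:
        raise RuntimeError("motif catalog must define exactly 10 classes")
    return tuple(classes)


def _matches(window: str, motif: MotifClass) -> bool:
    n = motif.length
    if len(window) < n:
        return False
    seg = window[-n:]
    if "N" in seg:
        return False
    pos = 0
    prev_char = None
    for run in motif.runs:
        block = seg[pos:pos + run]
        if block.count(block[0]) != run:
            return False
        if block[0] == prev_char:
            return False
        prev_char = block[0]
        pos += run
    return True


def match_motif(window: str) -> MotifClass | None:
    """Best-precedence motif whose 3' end abuts the end of ``window``.

    ``window`` is the (up to 7 nt) context immediately 5' of an A-site
    codon boundary; shorter windows near contig edges are allowed.
    """
    for motif in load_catalog():
        if _matches(window, motif):
            return motif
    return None


def scan_region(region: OverlapRegion, codon_usage: Mapping[str, float]
                ) -> list[SlipperyCandidate]:
    """Test every in-frame codon boundary of the window for a slippery site.

    Backward motifs are reported unconditionally; forward motifs only when
    the +1-frame A-site codon is more frequent than the in-frame one.
    """
    view = region.view
    out: list[SlipperyCandidate] = []
    for p in region.codon_boundaries():
        if p + 3 > view.length:
            continue
        window = view.seq[max(0, p - MOTIF_WINDOW):p]
        for motif in load_catalog():
            if not _matches(window, motif):
                continue
            if motif.direction == 1:
                a0 = view.seq[p:p + 3]
                a1 = view.seq[p + 1:p + 4]
                if len(a1) < 3 or "N" in a0 or "N" in a1:
                    continue
                if codon_usage.get(a1, 0.0) <= codon_usage.get(a0, 0.0):
                    continue
            out.append(SlipperyCandidate(
                region=region, a_site_pos=p, motif=motif,
                motif_span=(p - motif.length, p),
                direction=motif.direction))
            break
    return out


def label_candidates(candidates: list[SlipperyCandidate],
                     annotated_shift_pos: int | None,
                     annotated_direction: int | None = None,
                     radius: int = LABEL_RADIUS
                     ) -> list[tuple[SlipperyCandidate, int]]:
    """Label candidates against an annotated shift position.

    Candidates within ``radius`` bp of the annotation get the join's shift
    direction; everything else (including all candidates of non-joined
    pairs, ``annotated_shift_pos=None``) is labelled 0.
    """
    labelled = []
    for cand in candidates:
        label = 0
        if annotated_shift_pos is not None and \
                abs(cand.a_site_pos - annotated_shift_pos) <= radius:
            label = annotated_direction if annotated_direction is not None \
                else cand.direction
        labelled.append((cand, label))
    return labelled
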