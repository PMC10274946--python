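"""Join classification, joined-gene splitting, and overlap-region discovery.

A programmed ribosomal frameshift fuses two consecutive same-strand genes
whose reading frames differ.  The shift can only happen inside the
codon-bounded window that is (a) free of stop codons in the downstream
gene's frame and (b) 5' of the upstream gene's own in-frame stop codon.
This module finds those windows.

All positions here are 0-based half-open *view* coordinates: the genome is
re-oriented per strand (reverse strand genes are analysed on the reverse
complement) so that translation always runs left to right.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import is_stop, revcomp
from .genbank_io import CDSFeature, GenomeRecord, Location

__all__ = [
    "JoinClass",
    "Gene",
    "OverlapRegion",
    "GenomeView",
    "classify_join",
    "split_joined",
    "find_overlap_regions",
    "JOIN_SEPARATION_THRESHOLD",
    "JOIN_FRAGMENT_COUNT",
]

# A two-fragment joined CDS is taken as a frameshift only when its fragments
# are at most this many nucleotides apart; wider separations indicate
# inteins, introns, or annotation errors.
JOIN_SEPARATION_THRESHOLD = 10
JOIN_FRAGMENT_COUNT = 2


@dataclass(frozen=True)
class JoinClass:
    kind: str  # {"frameshift", "circular_wrap", "other"}
    fragment_separation: int
    n_fragments: int


def _separation(feature: CDSFeature) -> int:
    """Nucleotide gap between the first two fragments, along translation.

    0 means abutting fragments (the backward-shift annotation convention),
    1 a single skipped base (forward), negative an overlap.
    """
    a, b = feature.locations[0], feature.locations[1]
    if feature.strand == 1:
        return b.start - a.end - 1
    return a.start - b.end - 1


def classify_join(feature: CDSFeature, genome: GenomeRecord,
                  threshold: int = JOIN_SEPARATION_THRESHOLD) -> JoinClass:
    """Decide what a ``join``-annotated CDS represents.

    Two fragments within ``threshold`` bp of each other -> frameshift;
    fragments abutting opposite ends of a circular genome -> circular wrap;
    everything else (inteins, introns, wide separations, >2 fragments)
    -> other.
    """
    if not feature.is_joined:
        raise ValueError("classify_join requires a joined feature")
    n = len(feature.locations)
    if n == JOIN_FRAGMENT_COUNT:
        lo = min(feature.locations, key=lambda l: l.start)
        hi = max(feature.locations, key=lambda l: l.start)
        if genome.circular and lo.start == 1 and hi.end == len(genome.sequence):
            return JoinClass("circular_wrap", _separation(feature), n)
        sep = _separation(feature)
        if abs(sep) <= threshold:
            return JoinClass("frameshift", sep, n)
        return JoinClass("other", sep, n)
    return JoinClass("other", _separation(feature), n)


def split_joined(feature: CDSFeature) -> tuple[CDSFeature, CDSFeature]:
    """Split a frameshift-class joined CDS into its two pseudo-genes.

    Fragments are returned in biological 5'->3' order; the union of their
    spans equals the original compound location.
    """
    if len(feature.locations) != JOIN_FRAGMENT_COUNT or \
            abs(_separation(feature)) > JOIN_SEPARATION_THRESHOLD:
        raise ValueError("split_joined expects a frameshift-class join")
    a, b = feature.locations
    return (CDSFeature([a], product=feature.product),
            CDSFeature([b], product=feature.product))


class GenomeView:
    """A strand-oriented, 0-based view of a genome.

    On the reverse strand the view sequence is the reverse complement, so
    genes always read left to right and frames are simply ``start % 3``.
    """

    def __init__(self, record: GenomeRecord, strand: int):
        self.record = record
        self.strand = strand
        self.length = len(record.sequence)
        self.seq = record.sequence if strand == 1 else revcomp(record.sequence)

    def loc_to_view(self, loc: Location) -> tuple[int, int]:
        s0, e0 = loc.as_zero_based()
        if self.strand == 1:
            return s0, e0
        return self.length - e0, self.length - s0

    def view_to_location(self, start: int, end: int) -> Location:
        """Map a view interval back to a 1-based genome Location."""
        if self.strand == 1:
            return Location(start + 1, end, 1)
        return Location(self.length - end + 1, self.length - start, -1)

    def __getitem__(self, item) -> str:
        return self.seq[item]


@dataclass
class Gene:
    """A (possibly pseudo-) gene interval on a GenomeView."""

    start: int
    end: int
    feature: CDSFeature
    from_join: bool = False
    # View position of the annotated fragment boundary and the shift
    # direction implied by the fragment frames, for genes that came from
    # splitting a joined CDS.
    annotated_boundary: int | None = None
    annotated_direction: int | None = None

    @property
    def frame(self) -> int:
        return self.start % 3


@dataclass
class OverlapRegion:
    """The stop-free window where a frameshift could fuse geneA and geneB."""

    view: GenomeView
    gene_a: Gene
    gene_b: Gene
    window_start: int
    window_end: int          # end of geneA's +0 stop codon
    stop_a_start: int        # first base of geneA's +0 stop codon
    upstream_stop_offset_codons: int

    @property
    def strand(self) -> int:
        return self.view.strand

    @property
    def _from_one_join(self) -> bool:
        return (self.gene_a.from_join and self.gene_b.from_join and
                self.gene_a.annotated_boundary == self.gene_b.annotated_boundary)

    @property
    def annotated_boundary(self) -> int | None:
        return self.gene_a.annotated_boundary if self._from_one_join else None

    @property
    def annotated_direction(self) -> int | None:
        return self.gene_a.annotated_direction if self._from_one_join else None

    def codon_boundaries(self) -> range:
        """A-site codon starts (geneA's frame) available to a shift."""
        fa = self.gene_a.frame
        first = self.window_start + (-(self.window_start - fa)) % 3
        return range(first, self.stop_a_start - 2, 3)


def frame_shift_direction(frame_a: int, frame_b: int) -> int | None:
    """-1/+1 shift that moves frame_a into frame_b; None if frames equal."""
    d = (frame_b - frame_a) % 3
    return {0: None, 1: 1, 2: -1}[d]


def _genes_on_strand(genome: GenomeRecord, view: GenomeView,
                     join_threshold: int) -> list[Gene]:
    genes: list[Gene] = []
    for feat in genome.features:
        if feat.strand != view.strand:
            continue
        if feat.is_joined:
            jc = classify_join(feat, genome, threshold=join_threshold)
            if jc.kind != "frameshift":
                continue
            frag_a, frag_b = split_joined(feat)
            sa, ea = view.loc_to_view(frag_a.locations[0])
            sb, eb = view.loc_to_view(frag_b.locations[0])
            direction = frame_shift_direction(sa % 3, sb % 3)
            genes.append(Gene(sa, ea, frag_a, from_join=True,
                              annotated_boundary=ea,
                              annotated_direction=direction))
            genes.append(Gene(sb, eb, frag_b, from_join=True,
                              annotated_boundary=ea,
                              annotated_direction=direction))
        else:
            s, e = view.loc_to_view(feat.locations[0])
            genes.append(Gene(s, e, feat))
    genes.sort(key=lambda g: (g.start, g.end))
    # drop genes strictly contained in another gene: no consecutive-pair
    # semantics apply to them
    kept: list[Gene] = []
    for i, g in enumerate(genes):
        contained = any(
            (h.start <= g.start and g.end <= h.end) and
            (h.start < g.start or g.end < h.end)
            for h in genes if h is not g)
        if not contained:
            kept.append(g)
    return kept


def _first_downstream_stop(view: GenomeView, frame: int, from_pos: int,
                           limit: int = 600) -> int | None:
    """First in-frame stop codon start at or after ``from_pos`` (same frame)."""
    p = from_pos + (-(from_pos - frame)) % 3
    end = min(view.length - 2, p + limit)
    while p < end:
        if is_stop(view.seq[p:p + 3]):
            return p
        p += 3
    return None


def _nearest_upstream_stop(view: GenomeView, frame: int, before: int) -> int | None:
    """Start of the closest in-frame stop codon strictly 5' of ``before``."""
    p = before - 3
    while p >= 0:
        if is_stop(view.seq[p:p + 3]):
            return p
        p -= 3
    return None


def find_overlap_regions(genome: GenomeRecord,
                         join_threshold: int = JOIN_SEPARATION_THRESHOLD
                         ) -> list[OverlapRegion]:
    """Find every window where a frameshift could fuse consecutive genes.

    Joined features classified as frameshifts are first split into their
    pseudo gene pairs.  For each consecutive same-strand pair in coordinate
    order whose frames differ, the window runs from just after the nearest
    stop upstream of geneB (in geneB's frame) to the end of geneA's +0
    in-frame stop codon; pairs whose window never reaches into geneA, and
    opposite-strand pairs, yield nothing.
    """
    regions: list[OverlapRegion] = []
    for strand in (1, -1):
        view = GenomeView(genome, strand)
        genes = _genes_on_strand(genome, view, join_threshold)
        for ga, gb in zip(genes, genes[1:]):
            if gb.frame == ga.frame:
                continue
            stop_a = _first_downstream_stop(view, ga.frame, max(ga.end - 3, 0))
            if stop_a is None:
                continue
            up = _nearest_upstream_stop(view, gb.frame, gb.start)
            if up is None:
                window_start = gb.start % 3
                offset = (gb.start - window_start) // 3
            else:
                window_start = up + 3
                offset = (gb.start - up) // 3
            # a shift cannot precede the start of geneA's translation
            window_start = max(window_start, ga.start)
            window_end = stop_a + 3
            if window_start >= ga.end:      # window never reaches into geneA
                continue
            if window_start >= stop_a:      # no room for a shift
                continue
            region = OverlapRegion(
                view=view, gene_a=ga, gene_b=gb,
                window_start=window_start, window_end=window_end,
                stop_a_start=stop_a,
                upstream_stop_offset_codons=offset,
            )
            if len(region.codon_boundaries()) == 0:
                continue
            regions.append(region)
    return regions
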