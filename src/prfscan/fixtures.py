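"""Synthetic annotated genomes with planted frameshift signals.

Every pipeline stage is testable without downloads: this module builds
GenBank-ready genomes containing ordinary genes plus, optionally,

* a *planted PRF gene* — a joined CDS whose two fragments meet at a
  slippery site dressed with the full signal set: a chosen motif ending on
  a codon boundary, an AGGAGG element upstream of the P-site, a GC
  inverted-repeat hairpin at offset 3 downstream, and a nearby in-frame
  stop (small N);
* a *decoy pair* — two separate overlapping genes whose window contains a
  slippery motif but none of the other signals and a large N, giving the
  classifier realistic negative regions.

Codon usage is skewed per genome by sampling coding codons from a
Dirichlet-perturbed table, so the forward-shift A1 > A0 abundance gate can
be exercised both ways.  Output is deterministic per seed, and every
planted site is discoverable by the candidate scanner (generator-scanner
closure, enforced by the geometric constraints below and verified in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import STOP_CODONS, revcomp
from .genbank_io import CDSFeature, GenomeRecord, Location
from .motifs import MotifClass, load_catalog

__all__ = [
    "PlantedPRF",
    "FixtureSpec",
    "TruthSite",
    "make_genome",
    "make_corpus",
    "CorpusGenome",
]

_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
_SENSE_CODONS = tuple(c for c in _CODONS if c not in STOP_CODONS)


@dataclass(frozen=True)
class PlantedPRF:
    """What to plant at the fragment boundary of the joined gene."""

    motif_name: str = "threethree"
    n_distance: int = 24          # nt, slippery site to the +0 stop codon
    sd: bool = True               # AGGAGG element upstream of the P-site
    hairpin_stem: int = 8         # bp of GC stem at offset 3; 0 disables
    strand: int | None = None     # None -> drawn from the seed


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    genome_length: int = 7000     # approximate; assembly decides exactly
    gc: float = 0.60
    n_genes: int = 5              # ordinary background genes
    prf: PlantedPRF | None = field(default_factory=PlantedPRF)
    decoy: bool = True
    name: str | None = None


@dataclass(frozen=True)
class TruthSite:
    genome_name: str
    strand: int
    a_site_view: int              # A-site codon start, view coordinates
    boundary_view: int            # annotated fragment boundary, view coords
    direction: int
    motif_name: str


@dataclass(frozen=True)
class CorpusGenome:
    record: GenomeRecord
    truth: list[TruthSite]
    group: int                    # coarse-level cluster label


class InfeasibleSpec(ValueError):
    pass


def _motif_by_name(name: str) -> MotifClass:
    for m in load_catalog():
        if m.name == name:
            return m
    raise InfeasibleSpec(f"unknown motif class {name!r}")


def _sample_codons(rng, weights, n: int) -> str:
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=weights)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _motif_string(rng, motif: MotifClass) -> str:
    """Instantiate run letters; adjacent runs differ, stops avoided later."""
    letters = []
    prev = None
    for _ in motif.runs:
        choices = [b for b in "ACGT" if b != prev]
        prev = choices[rng.integers(len(choices))]
        letters.append(prev)
    return "".join(l * r for l, r in zip(letters, motif.runs))


def _has_stop(seq: str, start: int, end: int, frame_pos: int) -> bool:
    """Any stop codon on boundaries congruent to frame_pos within [start,end)."""
    p = start + (frame_pos - start) % 3
    while p + 3 <= end:
        if seq[p:p + 3] in STOP_CODONS:
            return True
        p += 3
    return False


def _build_cassette(rng, weights, usage: dict[str, float], *,
                    motif: MotifClass, sd: bool, hairpin_stem: int,
                    n_distance: int, joined: bool,
                    body_codons: int = 20, tail_codons: int = 15):
    """Assemble one overlap cassette; returns (seq, fragments, a_site, boundary).

    Layout (cassette coordinates, geneA frame = 0):
      ATG . body . [SD] [motif] | A-site | hairpin+filler . TAA . geneB tail
    with the fragment boundary placed by the annotation convention:
    separation 0 (backward) or 1 (forward).
    """
    direction = motif.direction
    if n_distance % 3 or n_distance < 6:
        raise InfeasibleSpec("n_distance must be a positive multiple of 3")
    hairpin_len = 2 * hairpin_stem + 3 if hairpin_stem else 0
    if hairpin_len and n_distance < hairpin_len + 3:
        raise InfeasibleSpec("hairpin longer than the stop-distance window")

    p = 3 + 3 * body_codons                       # A-site codon start
    ml = motif.length
    if p - 17 < 3:
        raise InfeasibleSpec("body too short for the SD element")

    for _ in range(300):
        seq = list("ATG" + _sample_codons(rng, weights, body_codons))
        if sd:
            seq[p - 16:p - 10] = "AGGAGG"
        mstr = _motif_string(rng, motif)
        seq[p - ml:p] = mstr
        if p - ml - 3 >= 3:
            # guard bases: keep the 5'-most run from extending further 5',
            # and keep the preceding bases from forming a spurious run that
            # would upgrade the planted motif to a rarer class
            g1 = [b for b in "ACG" if b != mstr[0]]
            seq[p - ml - 1] = g1[rng.integers(len(g1))]
            for back in (2, 3):
                g = [b for b in "ACG" if b != seq[p - ml - back + 1]]
                seq[p - ml - back] = g[rng.integers(len(g))]

        # overlap fill between the A-site codon and the +0 stop, built
        # first so the forward-gate codon choice can see its first base
        if hairpin_stem:
            stem = "".join(rng.choice(["G", "C"], size=hairpin_stem))
            spare = n_distance - 3 - hairpin_len
            fill = stem + "ACA" + revcomp(stem) + \
                "".join(rng.choice(["A", "C", "G"], size=spare))
        else:
            fill = "".join(rng.choice(["A", "C", "G"], size=n_distance - 3))

        # A-site codon: not a stop; must not create a stop on the geneB
        # frame boundary straddling the motif/A-site junction; forward
        # shifts must pass the A1 > A0 abundance gate with margin to spare
        # (the scanner re-evaluates the gate on the assembled genome's
        # computed usage, which jitters around the generative table).
        b_frame_rel = 2 if direction == -1 else 1   # geneB frame offset vs p
        candidates = []
        for codon in _SENSE_CODONS:
            if direction == -1:
                straddle = mstr[-1] + codon[0] + codon[1]
                if straddle in STOP_CODONS:
                    continue
                candidates.append((0.0, codon))
            else:
                shifted = codon[1] + codon[2] + fill[0]
                margin = usage.get(shifted, 0.0) - usage.get(codon, 0.0)
                if margin > 0.02:
                    candidates.append((-margin, codon))
        if not candidates:
            continue
        if direction == -1:
            a_codon = candidates[rng.integers(len(candidates))][1]
        else:
            candidates.sort()
            a_codon = candidates[0][1]
        seq += a_codon
        seq += fill
        seq += "TAA"                                  # geneA's +0 stop

        # geneB tail beyond geneA's stop, in geneB's frame, ending in a stop
        b_start = p + b_frame_rel
        join_fill = 2 if direction == -1 else 1
        seq += "".join(rng.choice(["A", "C", "G"], size=join_fill))
        seq += _sample_codons(rng, weights, tail_codons)
        seq += "TAA"
        s = "".join(seq)
        gene_b_end = len(s)

        # closure checks: the scanner must see exactly this geometry
        if s[b_start - 3:b_start] in STOP_CODONS:
            continue  # geneB-frame stop at the junction would exclude p
        if _has_stop(s, b_start, gene_b_end - 3, b_start % 3):
            continue  # premature stop in geneB's frame
        if _has_stop(s, p, p + n_distance, 0):
            continue  # premature +0 stop shrinks N

        boundary = p + 2 if direction == -1 else p
        if joined:
            frags = [(0, boundary), (boundary, gene_b_end)] \
                if direction == -1 else [(0, p), (p + 1, gene_b_end)]
        else:
            frags = [(0, p + n_distance + 3), (b_start, gene_b_end)]
        return s, frags, p, boundary
    raise InfeasibleSpec("could not satisfy cassette constraints")


def _ordinary_gene(rng, weights) -> str:
    n = int(rng.integers(30, 80))
    return "ATG" + _sample_codons(rng, weights, n) + "TAA"


def make_genome(spec: FixtureSpec) -> tuple[GenomeRecord, list[TruthSite]]:
    """Build one synthetic genome and the truth table of planted sites."""
    rng = np.random.default_rng(spec.seed)
    name = spec.name or f"synth{spec.seed}"
    weights = rng.dirichlet(np.full(len(_SENSE_CODONS), 2.0))
    usage = {c: w for c, w in zip(_SENSE_CODONS, weights)}

    # segments: (sequence, [(rel_start, rel_end, strand)], joined, meta)
    segments: list[tuple] = []

    def add_intergenic():
        segments.append((_random_seq(rng, int(rng.integers(20, 60)), spec.gc),
                         [], False, None))

    add_intergenic()
    for _ in range(spec.n_genes):
        gene = _ordinary_gene(rng, weights)
        strand = 1 if rng.random() < 0.5 else -1
        s = gene if strand == 1 else revcomp(gene)
        segments.append((s, [(0, len(gene), strand)], False, None))
        add_intergenic()

    cassettes = []
    if spec.prf is not None:
        motif = _motif_by_name(spec.prf.motif_name)
        strand = spec.prf.strand
        if strand is None:
            strand = 1 if rng.random() < 0.5 else -1
        cassettes.append(("planted", motif, spec.prf, strand, True))
    if spec.decoy:
        decoy_prf = PlantedPRF(motif_name="threethree", n_distance=60,
                               sd=False, hairpin_stem=0)
        cassettes.append(("decoy", _motif_by_name("threethree"),
                          decoy_prf, 1 if rng.random() < 0.5 else -1, False))

    truth_specs = []
    for kind, motif, prf, strand, joined in cassettes:
        seq, frags, a_site, boundary = _build_cassette(
            rng, weights, usage, motif=motif, sd=prf.sd,
            hairpin_stem=prf.hairpin_stem, n_distance=prf.n_distance,
            joined=joined)
        s = seq if strand == 1 else revcomp(seq)
        locs = [(f[0], f[1], strand) for f in frags]
        segments.append((s, locs, joined, (kind, motif, a_site, boundary,
                                           strand, len(seq))))
        add_intergenic()

    # assemble, tracking absolute offsets
    parts = []
    offset = 0
    features: list[CDSFeature] = []
    placed = []     # (meta, insert_offset)
    for seg, locs, joined, meta in segments:
        if locs:
            cass_len = len(seg)
            def to_genome(rel_s, rel_e, strand):
                if strand == 1:
                    return offset + rel_s, offset + rel_e
                return offset + cass_len - rel_e, offset + cass_len - rel_s
            # the coordinate flip for minus-strand cassettes already yields
            # biological 5'->3' order (fragment 1 has the higher coordinates)
            g_locs = []
            for rel_s, rel_e, strand in locs:
                gs, ge = to_genome(rel_s, rel_e, strand)
                g_locs.append(Location(gs + 1, ge, strand))
            if joined:
                features.append(CDSFeature(g_locs, product="planted shift gene"))
            else:
                for loc in g_locs:
                    features.append(CDSFeature([loc], product="gene"))
            if meta is not None:
                placed.append((meta, offset))
        parts.append(seg)
        offset += len(seg)
    if offset < spec.genome_length:
        parts.append(_random_seq(rng, spec.genome_length - offset, spec.gc))
    genome_seq = "".join(parts)
    L = len(genome_seq)

    truth = []
    for (kind, motif, a_site, boundary, strand, cass_len), ins in placed:
        if kind != "planted":
            continue
        if strand == 1:
            a_view, b_view = ins + a_site, ins + boundary
        else:
            shift = L - ins - cass_len
            a_view, b_view = shift + a_site, shift + boundary
        truth.append(TruthSite(
            genome_name=name, strand=strand, a_site_view=a_view,
            boundary_view=b_view, direction=motif.direction,
            motif_name=motif.name))

    features.sort(key=lambda f: f.span)
    record = GenomeRecord(name=name, sequence=genome_seq,
                          circular=False, features=features)
    return record, truth


_BACKWARD_MOTIFS = ("threethree", "six", "fivetwo", "twofive",
                    "twofour", "threetwotwo", "five", "twoonefour")
_FORWARD_MOTIFS = ("three", "four")


def make_corpus(seed: int, n_backward: int = 40, n_forward: int = 10,
                n_empty: int = 10, n_groups: int = 5) -> list[CorpusGenome]:
    """A seeded corpus for training/validation experiments.

    Backward-planted genomes cycle through all eight backward motif
    classes, forward-planted through the two forward classes; ``n_empty``
    genomes carry no joined gene (decoys only).  Coarse group labels are
    dealt round-robin.
    """
    specs = []
    for i in range(n_backward):
        specs.append(PlantedPRF(motif_name=_BACKWARD_MOTIFS[i % 8]))
    for i in range(n_forward):
        specs.append(PlantedPRF(motif_name=_FORWARD_MOTIFS[i % 2]))
    specs.extend([None] * n_empty)

    corpus = []
    base = seed * 10_000 + 1
    for i, prf in enumerate(specs):
        spec = FixtureSpec(seed=base + i, prf=prf,
                           name=f"synth{seed}g{i:03d}")
        record, truth = make_genome(spec)
        corpus.append(CorpusGenome(record=record, truth=truth,
                                   group=i % n_groups))
    return corpus
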