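"""Assembly of the eleven-property feature vector for a slippery candidate.

The classifier sees, per candidate site: shift direction (DIR), two RBS
scores at the P-site (RBS1 28-bin, RBS2 frequency-based), the motif class
id (MOTIF), genome-wide usage of the in-frame and shifted A-site codons
(A0, A1), four normalised downstream-MFE values (LF50/LF100 from the
hairpin-style slot, HK50/HK100 from the pseudoknot-capable slot), and the
distance N in nt from the slippery site to the +0 in-frame stop codon.

N uses the convention: first base of the A-site codon to the first base of
the +0 stop codon, which yields small values (e.g. 15) for stop-adjacent
sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dna import revcomp
from .folding import DEFAULT_BACKEND, windowed_mfe
from .genbank_io import GenomeRecord
from .motifs import SlipperyCandidate
from .rbs import score_rbs_prodigal, score_rbs_rast

__all__ = [
    "FEATURE_COLUMNS",
    "CodonUsageTable",
    "codon_usage",
    "FoldingConfig",
    "SiteFeatures",
    "featurize",
]

FEATURE_COLUMNS = ("DIR", "RBS1", "RBS2", "MOTIF", "A0", "A1",
                   "LF50", "LF100", "HK50", "HK100", "N")

_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")


class CodonUsageTable(dict):
    """Relative frequency of each of the 64 codons over all coding genes.

    Stop codons are counted like any other codon, which makes them
    one-per-gene rare codons — deliberately, since a ribosome pausing on a
    rare (or stop) codon is itself a frameshift signal.
    """

    @property
    def total(self) -> float:
        return sum(self.values())


def codon_usage(genome: GenomeRecord) -> CodonUsageTable:
    """Count in-frame codons of every CDS and normalise to frequencies.

    Joined features are counted over their fragment-concatenated reading
    frame; trailing partial codons and codons containing N are skipped.
    Raises ``ValueError`` when the genome yields no codons at all.
    """
    counts = dict.fromkeys(_CODONS, 0)
    for feat in genome.features:
        parts = []
        for loc in feat.locations:
            s0, e0 = loc.as_zero_based()
            frag = genome.sequence[s0:e0]
            parts.append(frag if loc.strand == 1 else revcomp(frag))
        coding = "".join(parts)
        for i in range(0, len(coding) - 2, 3):
            codon = coding[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome has no countable codons in its CDS features")
    return CodonUsageTable({c: n / total for c, n in counts.items()})


@dataclass(frozen=True)
class FoldingConfig:
    """Which folding backend fills each window slot, and the window sizes.

    Both slots default to the built-in nested folder; a hairpin-only engine
    belongs in ``lf_backend`` and a pseudoknot-capable one in
    ``hk_backend`` when available.
    """

    lf_backend: str = DEFAULT_BACKEND
    hk_backend: str = DEFAULT_BACKEND
    windows: tuple[int, int] = (50, 100)


@dataclass(frozen=True)
class SiteFeatures:
    dir: int
    rbs1: int
    rbs2: float
    motif: int
    a0: float
    a1: float
    lf50: float
    lf100: float
    hk50: float
    hk100: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.as_tuple()))

    def as_tuple(self) -> tuple:
        return (self.dir, self.rbs1, self.rbs2, self.motif, self.a0, self.a1,
                self.lf50, self.lf100, self.hk50, self.hk100, self.n)


def featurize(candidate: SlipperyCandidate, usage: CodonUsageTable,
              config: FoldingConfig | None = None) -> SiteFeatures:
    """Compute the eleven-property vector for one candidate site.

    Pure and deterministic given (candidate, usage, config).
    """
    config = config or FoldingConfig()
    region = candidate.region
    seq = region.view.seq
    p = candidate.a_site_pos

    a0_codon = seq[p:p + 3]
    if candidate.direction == -1:
        a1_codon = seq[max(p - 1, 0):p + 2]
    else:
        a1_codon = seq[p + 1:p + 4]
    a0 = usage.get(a0_codon, 0.0)
    a1 = usage.get(a1_codon, 0.0)

    w50, w100 = config.windows
    lf50 = windowed_mfe(seq, p, w50, config.lf_backend).value
    lf100 = windowed_mfe(seq, p, w100, config.lf_backend).value
    if config.hk_backend == config.lf_backend:
        hk50, hk100 = lf50, lf100
    else:
        hk50 = windowed_mfe(seq, p, w50, config.hk_backend).value
        hk100 = windowed_mfe(seq, p, w100, config.hk_backend).value

    return SiteFeatures(
        dir=candidate.direction,
        rbs1=score_rbs_prodigal(seq, p - 3),
        rbs2=score_rbs_rast(seq, p - 3),
        motif=candidate.motif.motif_id,
        a0=a0,
        a1=a1,
        lf50=lf50, lf100=lf100, hk50=hk50, hk100=hk100,
        n=region.stop_a_start - p,
    )
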