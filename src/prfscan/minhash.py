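"""MinHash genome sketching and Mash-style distance for 95%-identity groups.

Leakage-controlled validation needs genomes grouped by relatedness.  A
bottom-`size` MinHash sketch over canonical k-mers (default size 400,
k=16) estimates the k-mer Jaccard index j between two genomes, which the
Mash distance converts to an approximate per-base divergence:

    d = -(1/k) * ln(2j / (1 + j))

Single-linkage clustering of the distance graph at d <= 0.05 then yields
~95%-identity groups.  Hashing uses a fixed, documented 64-bit mixer
(splitmix64 over the 2-bit k-mer encoding, fixed seed) so sketches and
splits are reproducible across runs and machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genbank_io import GenomeRecord

__all__ = [
    "Sketch",
    "ClusterAssignment",
    "sketch",
    "jaccard_estimate",
    "mash_distance",
    "cluster_at",
    "DEFAULT_K",
    "DEFAULT_SKETCH_SIZE",
    "MASH95_THRESHOLD",
]

DEFAULT_K = 16
DEFAULT_SKETCH_SIZE = 400
MASH95_THRESHOLD = 0.05

_HASH_SEED = 0x5EED5EED5EED5EED
_MASK64 = (1 << 64) - 1
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


@dataclass(frozen=True)
class Sketch:
    genome_id: str
    k: int
    size: int
    hashes: tuple[int, ...]   # the `size` smallest hashes, ascending


@dataclass(frozen=True)
class ClusterAssignment:
    groups: dict[str, int]    # genome id -> group id (a partition)

    def __getitem__(self, genome_id: str) -> int:
        return self.groups[genome_id]


def _canonical_kmer_codes(seq: str, k: int):
    """2-bit codes of canonical k-mers (min of k-mer and revcomp); skips N."""
    n = len(seq)
    fwd = 0
    rev = 0
    valid = 0
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    for i, ch in enumerate(seq):
        code = _CODE.get(ch)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | (_COMP[code] << shift)
        valid += 1
        if valid >= k:
            yield min(fwd, rev)


def sketch(genome: GenomeRecord | str, k: int = DEFAULT_K,
           size: int = DEFAULT_SKETCH_SIZE,
           genome_id: str | None = None) -> Sketch:
    """Bottom-`size` sketch of canonical k-mer hashes.

    Accepts a GenomeRecord or a raw sequence string; raises when the
    sequence is shorter than k.
    """
    if isinstance(genome, GenomeRecord):
        seq, gid = genome.sequence, genome.name
    else:
        seq, gid = genome, genome_id or "sequence"
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    hashes = {_splitmix64(code ^ _HASH_SEED)
              for code in _canonical_kmer_codes(seq, k)}
    bottom = sorted(hashes)[:size]
    return Sketch(genome_id=gid, k=k, size=size, hashes=tuple(bottom))


def jaccard_estimate(s1: Sketch, s2: Sketch) -> float:
    """Jaccard index estimated from the merged bottom-`size` sketch."""
    if s1.k != s2.k or s1.size != s2.size:
        raise ValueError("sketches must share k and size")
    merged = sorted(set(s1.hashes) | set(s2.hashes))[:s1.size]
    shared = len(set(merged) & set(s1.hashes) & set(s2.hashes))
    return shared / len(merged) if merged else 0.0


def mash_distance(s1: Sketch, s2: Sketch) -> float:
    """Mash distance between two same-parameter sketches; 0 on identity,
    capped at 1 when the sketches share nothing."""
    if s1.hashes == s2.hashes and s1.k == s2.k and s1.size == s2.size:
        return 0.0
    j = jaccard_estimate(s1, s2)
    if j == 0.0:
        return 1.0
    return min(1.0, -(1.0 / s1.k) * math.log(2.0 * j / (1.0 + j)))


def cluster_at(genomes: list[GenomeRecord],
               threshold: float = MASH95_THRESHOLD,
               k: int = DEFAULT_K,
               size: int = DEFAULT_SKETCH_SIZE) -> ClusterAssignment:
    """Single-linkage clusters of the distance graph at d <= threshold.

    Group ids are assigned in order of each cluster's first genome, so the
    assignment is invariant to input order up to relabelling and stable for
    a fixed input list.
    """
    sketches = [sketch(g, k=k, size=size) for g in genomes]
    n = len(genomes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if mash_distance(sketches[i], sketches[j]) <= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    groups = {}
    for i, g in enumerate(genomes):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        groups[g.name] = roots[r]
    return ClusterAssignment(groups=groups)
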