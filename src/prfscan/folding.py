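"""Downstream RNA secondary-structure stability over fixed windows.

Stable structure just 3' of a slippery site pauses the ribosome and
promotes frameshifting.  The feature is the minimum free energy (MFE) of
the 50 bp and 100 bp windows starting immediately after the three A-site
bases (offset 3), normalised by window length and GC content so windows of
different composition are comparable:

    value = clamp(|mfe| / length / GC, 0, 1)

Folding goes through a pluggable backend contract (deterministic,
``mfe <= 0``).  The built-in ``baseline_nested`` backend is a
Nussinov-style dynamic program over nested pairings with simple pair
energies (GC -3, AU -2, GU -1 kcal/mol, minimum hairpin loop 3); an
``rnafold`` adapter uses the ViennaRNA ``RNAfold`` executable when it is
on PATH.  Dedicated hairpin- and pseudoknot-prediction engines can be
plugged in through the same contract.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .dna import gc_fraction

__all__ = [
    "FoldResult",
    "NormalizedMFE",
    "fold",
    "windowed_mfe",
    "normalize_mfe",
    "available_backends",
    "DEFAULT_BACKEND",
    "WINDOW_LENGTHS",
    "WINDOW_OFFSET",
]

DEFAULT_BACKEND = "baseline_nested"
WINDOW_LENGTHS = (50, 100)
WINDOW_OFFSET = 3           # window starts just after the 3 A-site bases

MIN_HAIRPIN_LOOP = 3
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# pair energies, kcal/mol; N is unpairable
_PAIR_E = np.zeros((5, 5), dtype=np.int64)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3        # G:C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2        # A:U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1        # G:U


@dataclass(frozen=True)
class FoldResult:
    mfe: float                 # kcal/mol, <= 0
    structure: str | None      # dot-bracket, same length as the window
    backend: str


@dataclass(frozen=True)
class NormalizedMFE:
    value: float               # dimensionless, in [0, 1]


def _nussinov_matrix(codes: np.ndarray) -> np.ndarray:
    """Minimum-energy matrix E[i, j] over nested pairings of codes[i..j]."""
    n = len(codes)
    diags = [np.zeros(n - d, dtype=np.int64) for d in range(n)]
    for d in range(1, n):
        m = n - d
        best = np.minimum(diags[d - 1][1:], diags[d - 1][:m])
        if d >= MIN_HAIRPIN_LOOP + 1:
            pe = _PAIR_E[codes[:m], codes[d:]]
            inner = diags[d - 2][1:m + 1] if d >= 2 else np.zeros(m, dtype=np.int64)
            paired = np.where(pe < 0, inner + pe, 0)
            best = np.minimum(best, paired)
        for k in range(1, d):
            best = np.minimum(best, diags[k][:m] + diags[d - 1 - k][k + 1:k + 1 + m])
        diags[d] = best
    E = np.zeros((n, n), dtype=np.int64)
    for d in range(n):
        idx = np.arange(n - d)
        E[idx, idx + d] = diags[d]
    return E


def _traceback(E: np.ndarray, codes: np.ndarray) -> str:
    n = len(codes)
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 1:
            continue
        e = E[i, j]
        if e == 0:
            continue
        if e == E[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if e == E[i, j - 1]:
            stack.append((i, j - 1))
            continue
        pe = _PAIR_E[codes[i], codes[j]]
        if pe < 0 and j - i > MIN_HAIRPIN_LOOP and \
                e == (E[i + 1, j - 1] if j - i >= 2 else 0) + pe:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if e == E[i, k] + E[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return "".join(structure)


def _fold_baseline(window: str) -> tuple[float, str | None]:
    codes = np.array([_BASE_CODE.get(c, 4) for c in window.upper()],
                     dtype=np.int64)
    if len(codes) == 1:
        return 0.0, "."
    E = _nussinov_matrix(codes)
    return float(E[0, -1]), _traceback(E, codes)


def _rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def _fold_rnafold(window: str) -> tuple[float, str | None]:
    if not _rnafold_available():
        raise RuntimeError("RNAfold executable not found on PATH")
    rna = window.upper().replace("T", "U")
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n",
        capture_output=True, text=True, check=True)
    last = proc.stdout.strip().splitlines()[-1]
    match = re.match(r"([.()]+)\s+\(\s*(-?\d+\.?\d*)\)", last)
    if not match:
        raise RuntimeError(f"could not parse RNAfold output: {last!r}")
    return min(float(match.group(2)), 0.0), match.group(1)


_BACKENDS = {
    "baseline_nested": _fold_baseline,
    "rnafold": _fold_rnafold,
}


def available_backends() -> list[str]:
    names = ["baseline_nested"]
    if _rnafold_available():
        names.append("rnafold")
    return names


@lru_cache(maxsize=16384)
def _fold_cached(window: str, backend: str) -> tuple[float, str | None]:
    return _BACKENDS[backend](window)


def fold(window: str, backend: str = DEFAULT_BACKEND) -> FoldResult:
    """Fold one window; deterministic, with ``mfe <= 0``.

    Raises on an empty window or an unknown backend.  N bases are treated
    as unpairable.
    """
    if not window:
        raise ValueError("cannot fold an empty window")
    if backend not in _BACKENDS:
        raise ValueError(f"unknown folding backend {backend!r}")
    mfe, structure = _fold_cached(window, backend)
    return FoldResult(mfe=mfe, structure=structure, backend=backend)


def normalize_mfe(mfe: float, window: str) -> NormalizedMFE:
    """|MFE| per base per unit GC, clamped to [0, 1]; 0 when GC = 0."""
    gc = gc_fraction(window)
    if not window or gc == 0.0:
        return NormalizedMFE(0.0)
    value = abs(mfe) / len(window) / gc
    return NormalizedMFE(min(max(value, 0.0), 1.0))


def windowed_mfe(seq: str, a_site_pos: int, window_len: int = 50,
                 backend: str = DEFAULT_BACKEND) -> NormalizedMFE:
    """Normalised MFE of the window just 3' of the A-site codon.

    ``seq`` is the coding-strand sequence, ``a_site_pos`` the 0-based start
    of the A-site codon; the window covers ``window_len`` bases starting at
    offset 3 (immediately after the A-site bases).  Windows truncated by
    the contig edge are folded and normalised at their actual length; a
    window entirely off the contig scores 0.0 with a warning.
    """
    start = a_site_pos + WINDOW_OFFSET
    window = seq[start:start + window_len]
    if not window:
        warnings.warn("fold window lies entirely off the contig; scoring 0.0")
        return NormalizedMFE(0.0)
    result = fold(window, backend=backend)
    return normalize_mfe(result.mfe, window)
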