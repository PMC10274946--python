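"""Shared fixtures: a worked two-gene GenBank file and a cached synthetic
corpus (featurization is the expensive step, so it is session-scoped)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from prfscan.features import FoldingConfig
from prfscan.fixtures import make_corpus
from prfscan.pipeline import genome_table


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60].lower()
        parts = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return "\n".join(lines)


def genbank_text(name: str, seq: str, feature_lines: list[str],
                 topology: str = "linear") -> str:
    """Minimal hand-built GenBank flat file."""
    head = (f"LOCUS       {name:<16} {len(seq)} bp    DNA     {topology}"
            f"   PHG 01-JAN-2000\n"
            f"DEFINITION  synthetic test record.\n"
            f"FEATURES             Location/Qualifiers\n")
    feats = "".join(f"     CDS             {line}\n" for line in feature_lines)
    return head + feats + "ORIGIN\n" + _origin_block(seq) + "\n//\n"


@pytest.fixture(scope="session")
def two_gene_text() -> str:
    """The worked example: one plain CDS and one joined CDS on 400 nt."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    return genbank_text(
        "EXAMPLE", seq,
        ['1..100\n                     /product="terminase"',
         'join(200..300,301..400)\n'
         '                     /product="tail assembly chaperone"'])


@pytest.fixture(scope="session")
def small_corpus():
    """12 synthetic genomes: 8 backward, 2 forward, 2 without a PRF."""
    return make_corpus(seed=7, n_backward=8, n_forward=2, n_empty=2)


@pytest.fixture(scope="session")
def corpus_tables(small_corpus):
    """Cached per-genome candidate tables + region inventories."""
    tables, inventories, regions_by_genome = {}, {}, {}
    for item in small_corpus:
        table, regions, _ = genome_table(item.record, FoldingConfig())
        tables[item.record.name] = table
        regions_by_genome[item.record.name] = regions
        inventories[item.record.name] = pd.DataFrame({
            "genome": item.record.name,
            "region_id": range(len(regions)),
            "region_positive": [r.annotated_boundary is not None
                                for r in regions],
        })
    return tables, inventories, regions_by_genome
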