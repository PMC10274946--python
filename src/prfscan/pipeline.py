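"""Shared candidate-extraction and featurization path.

Training, validation, and prediction all need the same table: one row per
slippery-site candidate with the eleven classifier features plus the
bookkeeping columns that tie the row back to its genome, overlap region,
and (when the genome carries ``join`` annotations) its training label.
"""

from __future__ import annotations

import pandas as pd

from .candidates import OverlapRegion, find_overlap_regions
from .features import FEATURE_COLUMNS, FoldingConfig, codon_usage, featurize
from .genbank_io import GenomeRecord
from .motifs import LABEL_RADIUS, SlipperyCandidate, label_candidates, scan_region

__all__ = ["META_COLUMNS", "genome_table", "corpus_table"]

META_COLUMNS = ("genome", "region_id", "strand", "a_site_view", "direction",
                "motif_name", "region_positive", "dist_to_annotation", "label")


def genome_table(genome: GenomeRecord,
                 config: FoldingConfig | None = None,
                 label_radius: int = LABEL_RADIUS
                 ) -> tuple[pd.DataFrame, list[OverlapRegion],
                            list[SlipperyCandidate]]:
    """Feature/metadata table for every candidate in one genome.

    Returns the table plus the region and candidate lists (row order
    matches the candidate list; ``region_id`` indexes the region list).
    """
    usage = codon_usage(genome) if genome.features else {}
    regions = find_overlap_regions(genome)
    rows = []
    all_cands: list[SlipperyCandidate] = []
    for ridx, region in enumerate(regions):
        cands = scan_region(region, usage)
        labelled = label_candidates(cands, region.annotated_boundary,
                                    region.annotated_direction,
                                    radius=label_radius)
        for cand, label in labelled:
            feats = featurize(cand, usage, config)
            boundary = region.annotated_boundary
            row = {
                "genome": genome.name,
                "region_id": ridx,
                "strand": region.strand,
                "a_site_view": cand.a_site_pos,
                "direction": cand.direction,
                "motif_name": cand.motif.name,
                "region_positive": boundary is not None,
                "dist_to_annotation": (abs(cand.a_site_pos - boundary)
                                       if boundary is not None else -1),
                "label": label,
            }
            row.update(feats.as_dict())
            rows.append(row)
            all_cands.append(cand)
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_COLUMNS))
    return table, regions, all_cands


def corpus_table(genomes: list[GenomeRecord],
                 config: FoldingConfig | None = None) -> pd.DataFrame:
    """Concatenated candidate tables for a corpus (one featurization pass)."""
    tables = [genome_table(g, config)[0] for g in genomes]
    if not tables:
        return pd.DataFrame(columns=list(META_COLUMNS) + list(FEATURE_COLUMNS))
    return pd.concat(tables, ignore_index=True)
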