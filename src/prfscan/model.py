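"""Three-class gradient-boosted classification of slippery sites.

A histogram gradient-boosting classifier maps each candidate's eleven
properties to one of three classes: -1 (backward shift), 0 (no shift),
+1 (forward shift).  Hyperparameters follow the reference configuration:
library defaults except L2 regularization 1.0 (to temper overtraining) and
early stopping off, which makes training and prediction deterministic for
fixed inputs.

Per overlap region only the highest-scoring candidate — the one with the
largest non-zero-class probability whose predicted class is non-zero — is
reported as the region's PRF call.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier

from .candidates import OverlapRegion
from .features import FEATURE_COLUMNS, FoldingConfig
from .genbank_io import CDSFeature, GenomeRecord, Location
from .minhash import cluster_at
from .motifs import LABEL_RADIUS, load_catalog
from .pipeline import genome_table

__all__ = [
    "ModelConfig",
    "PRFModel",
    "PRFCall",
    "Confusion",
    "ValidationResult",
    "train",
    "predict_genome",
    "validate",
    "calls_to_record",
    "VALIDATION_LEVELS",
]

VALIDATION_LEVELS = ("CLUSTER", "SUBCLUSTER", "MASH95", "GENOME")


@dataclass(frozen=True)
class ModelConfig:
    l2_regularization: float = 1.0
    early_stopping: bool = False
    random_state: int = 0
    label_radius: int = LABEL_RADIUS
    folding: FoldingConfig = field(default_factory=FoldingConfig)


@dataclass
class PRFModel:
    clf: HistGradientBoostingClassifier
    columns: tuple[str, ...]
    motif_ids: dict[str, int]
    config: ModelConfig

    def save(self, path) -> None:
        joblib.dump({
            "clf": self.clf,
            "columns": list(self.columns),
            "motif_ids": self.motif_ids,
            "config": asdict(self.config),
            "format_version": 1,
        }, path)

    @classmethod
    def load(cls, path) -> "PRFModel":
        blob = joblib.load(path)
        cfg = dict(blob["config"])
        cfg["folding"] = FoldingConfig(**cfg["folding"])
        return cls(clf=blob["clf"], columns=tuple(blob["columns"]),
                   motif_ids=blob["motif_ids"], config=ModelConfig(**cfg))


def train(table: pd.DataFrame, config: ModelConfig | None = None) -> PRFModel:
    """Fit the classifier on a candidate feature table with a label column.

    Raises on single-class input and on NaN features (naming the row).
    """
    config = config or ModelConfig()
    X = table[list(FEATURE_COLUMNS)]
    y = table["label"].to_numpy()
    nan_rows = np.where(X.isna().any(axis=1))[0]
    if nan_rows.size:
        raise ValueError(f"NaN feature in table row {nan_rows[0]}")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two label classes")
    clf = HistGradientBoostingClassifier(
        l2_regularization=config.l2_regularization,
        early_stopping=config.early_stopping,
        random_state=config.random_state,
    )
    clf.fit(X.to_numpy(), y)
    return PRFModel(clf=clf, columns=FEATURE_COLUMNS,
                    motif_ids={m.name: m.motif_id for m in load_catalog()},
                    config=config)


@dataclass(frozen=True)
class PRFCall:
    genome: str
    region_index: int
    direction: int            # predicted shift, -1 or +1
    score: float              # best non-zero-class probability
    a_site: Location          # A-site codon, 1-based genome coordinates
    fragment_a: Location      # implied joined-gene fragments
    fragment_b: Location
    motif_name: str
    n_distance: int


def _best_rows(sub: pd.DataFrame, model: PRFModel) -> pd.Series | None:
    """Best qualifying candidate row of one region, or None."""
    proba = model.clf.predict_proba(sub[list(FEATURE_COLUMNS)].to_numpy())
    classes = list(model.clf.classes_)
    shift_cols = [i for i, c in enumerate(classes) if c != 0]
    scores = proba[:, shift_cols].max(axis=1)
    pred = np.asarray(classes)[np.argmax(proba, axis=1)]
    qualifying = np.where(pred != 0)[0]
    if qualifying.size == 0:
        return None
    best = qualifying[np.argmax(scores[qualifying])]
    row = sub.iloc[best].copy()
    row["pred_direction"] = int(pred[best])
    row["pred_score"] = float(scores[best])
    return row


def _call_from_row(row: pd.Series, region: OverlapRegion) -> PRFCall:
    p = int(row["a_site_view"])
    direction = int(row["pred_direction"])
    view = region.view
    if direction == -1:
        frag_a = (region.gene_a.start, p + 2)
        frag_b = (p + 2, region.gene_b.end)
    else:
        frag_a = (region.gene_a.start, p)
        frag_b = (p + 1, region.gene_b.end)
    return PRFCall(
        genome=view.record.name,
        region_index=int(row["region_id"]),
        direction=direction,
        score=float(row["pred_score"]),
        a_site=view.view_to_location(p, p + 3),
        fragment_a=view.view_to_location(*frag_a),
        fragment_b=view.view_to_location(*frag_b),
        motif_name=str(row["motif_name"]),
        n_distance=int(row["N"]),
    )


def predict_genome(genome: GenomeRecord, model: PRFModel,
                   config: FoldingConfig | None = None) -> list[PRFCall]:
    """Predict at most one PRF site per overlap region of a genome."""
    table, regions, _ = genome_table(genome, config or model.config.folding)
    calls = []
    for ridx, sub in table.groupby("region_id"):
        row = _best_rows(sub, model)
        if row is not None:
            calls.append(_call_from_row(row, regions[int(ridx)]))
    calls.sort(key=lambda c: c.a_site.start)
    return calls


def calls_to_record(genome: GenomeRecord, calls: list[PRFCall]) -> GenomeRecord:
    """A copy of the genome with predicted joined CDS features appended."""
    features = list(genome.features)
    for call in calls:
        locs = [call.fragment_a, call.fragment_b]
        if locs[0].strand == 1:
            locs.sort(key=lambda l: l.start)
        else:
            locs.sort(key=lambda l: -l.start)
        features.append(CDSFeature(locs, product="predicted frameshift gene"))
    return GenomeRecord(name=genome.name, sequence=genome.sequence,
                        circular=genome.circular, features=features)


@dataclass
class Confusion:
    """Per-overlap-region confusion counts.

    A positive region (one whose gene pair came from a joined annotation)
    counts TP when the call lands within the label radius of the
    annotation, FN otherwise; a wrong-location call additionally counts
    FP.  Negative regions count FP when called, TN when not.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0


@dataclass
class ValidationResult:
    level: str
    predictions: pd.DataFrame     # one row per called region
    inventory: pd.DataFrame       # one row per region
    confusion: Confusion
    n_groups: int


def _group_labels(genomes: list[GenomeRecord], level: str,
                  groups: dict[str, object] | None) -> dict[str, object]:
    if level == "GENOME":
        return {g.name: g.name for g in genomes}
    if level == "MASH95":
        return dict(cluster_at(genomes).groups)
    if level in ("CLUSTER", "SUBCLUSTER"):
        if groups is None:
            raise ValueError(f"{level} validation needs external group labels")
        return {g.name: groups[g.name] for g in genomes}
    raise ValueError(f"unknown validation level {level!r}")


def validate(genomes: list[GenomeRecord], level: str = "GENOME",
             config: ModelConfig | None = None,
             groups: dict[str, object] | None = None,
             tables: dict[str, pd.DataFrame] | None = None,
             inventories: dict[str, pd.DataFrame] | None = None
             ) -> ValidationResult:
    """Leave-one-group-out validation over a corpus.

    For each group: train on the candidates of all other genomes, predict
    on the left-out genomes, merge.  ``tables``/``inventories`` may carry
    precomputed per-genome candidate tables (as from
    :func:`prfscan.pipeline.genome_table`) to share featurization across
    levels; otherwise they are computed here.
    """
    config = config or ModelConfig()
    labels = _group_labels(genomes, level, groups)
    if len(set(labels.values())) < 2:
        raise ValueError("leave-one-group-out needs at least two groups")
    if tables is None:
        tables, inventories = {}, {}
        for g in genomes:
            table, regions, _ = genome_table(g, config.folding,
                                             config.label_radius)
            tables[g.name] = table
            inventories[g.name] = pd.DataFrame({
                "genome": g.name,
                "region_id": range(len(regions)),
                "region_positive": [r.annotated_boundary is not None
                                    for r in regions],
            })
    full = pd.concat([tables[g.name] for g in genomes], ignore_index=True)
    inventory = pd.concat([inventories[g.name] for g in genomes],
                          ignore_index=True)

    called_rows = []
    for group in sorted(set(labels.values()), key=str):
        held = {name for name, lab in labels.items() if lab == group}
        train_tab = full[~full["genome"].isin(held)]
        model = train(train_tab, config)
        test_tab = full[full["genome"].isin(held)]
        for (gname, ridx), sub in test_tab.groupby(["genome", "region_id"]):
            row = _best_rows(sub, model)
            if row is not None:
                called_rows.append(row)

    pred_cols = ["genome", "region_id", "region_positive",
                 "dist_to_annotation", "pred_direction", "pred_score",
                 "a_site_view", "motif_name"]
    predictions = (pd.DataFrame(called_rows)[pred_cols]
                   if called_rows else pd.DataFrame(columns=pred_cols))

    conf = Confusion()
    called = {(r["genome"], r["region_id"]): r
              for _, r in predictions.iterrows()}
    for _, reg in inventory.iterrows():
        key = (reg["genome"], reg["region_id"])
        row = called.get(key)
        if reg["region_positive"]:
            if row is not None and \
                    0 <= row["dist_to_annotation"] <= config.label_radius:
                conf.tp += 1
            else:
                conf.fn += 1
                if row is not None:
                    conf.fp += 1
        else:
            if row is not None:
                conf.fp += 1
            else:
                conf.tn += 1
    return ValidationResult(level=level, predictions=predictions,
                            inventory=inventory, confusion=conf,
                            n_groups=len(set(labels.values())))
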