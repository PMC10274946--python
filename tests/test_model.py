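"""Classifier training, best-site prediction, and grouped validation."""

import numpy as np
import pandas as pd
import pytest

from prfscan.features import FEATURE_COLUMNS
from prfscan.fixtures import FixtureSpec, PlantedPRF, make_genome
from prfscan.model import (Confusion, ModelConfig, PRFModel, predict_genome,
                           train, validate, calls_to_record)


@pytest.fixture(scope="module")
def full_table(corpus_tables):
    tables, _, _ = corpus_tables
    return pd.concat(tables.values(), ignore_index=True)


@pytest.fixture(scope="module")
def fitted(full_table):
    return train(full_table, ModelConfig())


class TestTrain:
    def test_deterministic_repeat_training(self, full_table):
        m1 = train(full_table, ModelConfig())
        m2 = train(full_table, ModelConfig())
        X = full_table[list(FEATURE_COLUMNS)].to_numpy()
        assert np.array_equal(m1.clf.predict_proba(X), m2.clf.predict_proba(X))

    def test_single_class_refused(self, full_table):
        neg = full_table[full_table["label"] == 0]
        with pytest.raises(ValueError, match="two label classes"):
            train(neg, ModelConfig())

    def test_two_sparse_classes_train_gracefully(self, full_table):
        sub = pd.concat([full_table[full_table["label"] == 0].head(30),
                         full_table[full_table["label"] == -1].head(1)])
        model = train(sub, ModelConfig())
        assert set(model.clf.classes_) == {-1, 0}

    def test_nan_feature_named(self, full_table):
        bad = full_table.head(10).copy().reset_index(drop=True)
        bad.loc[4, "A0"] = np.nan
        with pytest.raises(ValueError, match="row 4"):
            train(bad, ModelConfig())

    def test_separable_planted_signal_high_training_accuracy(
            self, full_table, fitted):
        X = full_table[list(FEATURE_COLUMNS)].to_numpy()
        y = full_table["label"].to_numpy()
        assert fitted.clf.score(X, y) > 0.95

    def test_save_load_round_trip(self, tmp_path, fitted, full_table):
        path = tmp_path / "model.joblib"
        fitted.save(path)
        back = PRFModel.load(path)
        assert back.columns == fitted.columns
        assert back.motif_ids == fitted.motif_ids
        X = full_table[list(FEATURE_COLUMNS)].to_numpy()
        assert np.array_equal(back.clf.predict_proba(X),
                              fitted.clf.predict_proba(X))


class TestPredict:
    def test_planted_genome_yields_one_call_at_the_site(self, fitted):
        rec, truth = make_genome(FixtureSpec(seed=901))
        calls = predict_genome(rec, fitted)
        t = truth[0]
        matching = [c for c in calls if c.direction == t.direction]
        assert len(calls) >= 1
        assert len(matching) == 1
        # the call's A-site must land within the label radius of the truth
        call = matching[0]
        strand = call.a_site.strand
        assert strand == t.strand
        from prfscan.candidates import GenomeView
        view = GenomeView(rec, strand)
        s0, _ = call.a_site.as_zero_based()
        view_pos = s0 if strand == 1 else len(rec.sequence) - s0 - 3
        assert abs(view_pos - t.a_site_view) <= 10

    def test_genome_without_overlaps_yields_nothing(self, fitted):
        from prfscan.genbank_io import CDSFeature, GenomeRecord, Location
        genome = GenomeRecord("LONE", "ATG" + "GCA" * 20 + "TAA" + "C" * 40,
                              features=[CDSFeature([Location(1, 66, 1)])])
        assert predict_genome(genome, fitted) == []

    def test_best_site_rule(self, fitted):
        """The reported candidate's score tops every qualifying candidate."""
        from prfscan.pipeline import genome_table
        rec, _ = make_genome(FixtureSpec(seed=902))
        table, _, _ = genome_table(rec)
        calls = predict_genome(rec, fitted)
        by_region = {c.region_index: c for c in calls}
        for ridx, sub in table.groupby("region_id"):
            proba = fitted.clf.predict_proba(sub[list(FEATURE_COLUMNS)].to_numpy())
            classes = np.asarray(fitted.clf.classes_)
            pred = classes[np.argmax(proba, axis=1)]
            shift_scores = proba[:, classes != 0].max(axis=1)
            qualifying = shift_scores[pred != 0]
            if int(ridx) in by_region:
                assert by_region[int(ridx)].score == pytest.approx(
                    qualifying.max())
            else:
                assert qualifying.size == 0

    def test_end_to_end_determinism(self, fitted):
        rec, _ = make_genome(FixtureSpec(seed=903))
        assert predict_genome(rec, fitted) == predict_genome(rec, fitted)

    def test_predicted_join_round_trips_through_genbank(self, fitted):
        from prfscan.genbank_io import read_genbank, write_genbank
        rec, _ = make_genome(FixtureSpec(seed=904))
        calls = predict_genome(rec, fitted)
        assert calls
        annotated = calls_to_record(rec, calls)
        text = write_genbank([annotated])
        back = read_genbank(text)[0]
        joined = [f for f in back.features
                  if f.is_joined and f.product == "predicted frameshift gene"]
        assert len(joined) == len(calls)


class TestValidate:
    def test_logo_bookkeeping_and_double_entry(self, small_corpus,
                                               corpus_tables):
        tables, inventories, _ = corpus_tables
        genomes = [c.record for c in small_corpus]
        groups = {c.record.name: c.group for c in small_corpus}
        res = validate(genomes, level="CLUSTER", groups=groups,
                       tables=tables, inventories=inventories)
        c = res.confusion
        n_regions = len(res.inventory)
        n_positive = int(res.inventory["region_positive"].sum())
        assert c.tp + c.fn == n_positive
        # double-entry oracle: recount the confusion from the tables
        recount = Confusion()
        called = {(r["genome"], r["region_id"]): r
                  for _, r in res.predictions.iterrows()}
        for _, reg in res.inventory.iterrows():
            row = called.get((reg["genome"], reg["region_id"]))
            if reg["region_positive"]:
                if row is not None and 0 <= row["dist_to_annotation"] <= 10:
                    recount.tp += 1
                else:
                    recount.fn += 1
                    if row is not None:
                        recount.fp += 1
            elif row is not None:
                recount.fp += 1
            else:
                recount.tn += 1
        assert (recount.tp, recount.fp, recount.tn, recount.fn) == \
               (c.tp, c.fp, c.tn, c.fn)
        assert c.tp + c.fn + c.tn <= n_regions

    def test_genome_level_uses_one_group_per_genome(self, small_corpus,
                                                    corpus_tables):
        tables, inventories, _ = corpus_tables
        genomes = [c.record for c in small_corpus]
        res = validate(genomes, level="GENOME", tables=tables,
                       inventories=inventories)
        assert res.n_groups == len(genomes)

    def test_single_group_is_an_error(self, small_corpus, corpus_tables):
        tables, inventories, _ = corpus_tables
        genomes = [c.record for c in small_corpus]
        groups = {g.name: "all" for g in genomes}
        with pytest.raises(ValueError, match="two groups"):
            validate(genomes, level="CLUSTER", groups=groups,
                     tables=tables, inventories=inventories)

    def test_unknown_level_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            validate([c.record for c in small_corpus], level="PHYLUM")
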