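"""Design grid, forest training, and decision-path extraction."""

import numpy as np
import pandas as pd
import pytest

from afpom import experiment_ml as ml
from afpom import synthetic_data as sd
from afpom.cell_model import IonicProfile, MULTIPLIER_NAMES
from afpom.errors import DegenerateLabelError, RangeError, SchemaError
from afpom.population import sample_profiles


def _labeled(n=1000, rule="gk1_threshold", seed=0, noise=None):
    return sd.gen_outcome_table(n, rule, seed=seed, noise=noise)


class TestBuildDesign:
    def test_grid_cardinality_127_profiles(self):
        profiles = sample_profiles(127, seed=5)
        table = ml.build_design(profiles)
        assert len(table) == 127 * 2 * 4 == 1016

    def test_single_cell_grid(self):
        table = ml.build_design([IonicProfile("p")], ["normal"], ["basal"])
        assert len(table) == 1

    def test_basal_rows_carry_raw_multipliers(self):
        prof = IonicProfile("p", m_gNa=1.5, m_gCaL=0.8)
        table = ml.build_design([prof])
        basal = table[table.condition == "basal"].iloc[0]
        assert basal.m_gNa == pytest.approx(1.5)
        assert basal.m_gCaL == pytest.approx(0.8)
        # drugs move the effective multipliers off the raw values
        vera = table[table.condition == "verapamil"].iloc[0]
        assert vera.m_gCaL == pytest.approx(0.8 / 6.0)
        assert vera.m_gNa == pytest.approx(1.5 / 1.5)
        iso = table[table.condition == "isoproterenol"].iloc[0]
        assert iso.m_gCaL == pytest.approx(0.8 * 1.8)

    def test_deterministic_ordering(self):
        profiles = [IonicProfile("a"), IonicProfile("b")]
        table = ml.build_design(profiles)
        assert list(table.profile_id[:8]) == ["a"] * 8
        assert list(table.tissue[:8]) == ["normal"] * 4 + ["dilated"] * 4

    def test_duplicate_profile_id_rejected(self):
        with pytest.raises(RangeError):
            ml.build_design([IonicProfile("a"), IonicProfile("a")])


class TestTrainClassifier:
    def test_rule_recovery_accuracy_and_importance(self):
        table = _labeled(1000)
        clf = ml.train_classifier(table, seed=0)
        assert clf.holdout_accuracy >= 0.98
        imp = clf.importances.sort_values(ascending=False)
        assert imp.index[0] == "m_gK1"
        assert imp.iloc[0] >= 2 * imp.iloc[1]
        assert clf.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(clf.cv_scores) == 5

    def test_permuted_labels_fall_to_chance(self, rng):
        table = _labeled(1000)
        table = table.copy()
        table["label"] = rng.permutation(table["label"].to_numpy())
        clf = ml.train_classifier(table, seed=0)
        majority = table["label"].value_counts(normalize=True).max()
        # binomial noise around the majority-class rate on 200 held-out rows
        assert abs(clf.holdout_accuracy - majority) < 0.12

    def test_single_class_rejected(self):
        table = _labeled(100)
        table["label"] = "induced"
        with pytest.raises(DegenerateLabelError):
            ml.train_classifier(table)

    def test_seed_determinism(self):
        table = _labeled(600)
        a = ml.train_classifier(table, seed=3)
        b = ml.train_classifier(table, seed=3)
        assert np.array_equal(a.cv_scores, b.cv_scores)
        assert a.holdout_accuracy == b.holdout_accuracy

    def test_duplicated_table_preserves_dominant_feature(self):
        """Doubling every row leaves the learned rule unchanged: the
        informative feature stays on top and keeps dominating."""
        table = _labeled(600)
        doubled = pd.concat([table, table], ignore_index=True)
        a = ml.train_classifier(table, seed=0)
        b = ml.train_classifier(doubled, seed=0)
        assert a.importances.idxmax() == b.importances.idxmax() == "m_gK1"
        for clf in (a, b):
            imp = clf.importances.sort_values(ascending=False)
            assert imp.iloc[0] >= 2 * imp.iloc[1]


class TestPredict:
    def test_training_row_recalled_with_high_probability(self):
        table = _labeled(800)
        clf = ml.train_classifier(table, seed=1)
        row = table.iloc[0]
        label, p_induced = ml.predict_inducibility(clf, row)
        assert label == row["label"]
        p = p_induced if label == "induced" else 1.0 - p_induced
        assert p > 0.9

    def test_probabilities_sum_to_one(self):
        table = _labeled(400)
        clf = ml.train_classifier(table, seed=1)
        X = table[clf.features].to_numpy(dtype=float)
        proba = clf.forest.predict_proba(X[:16])
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_schema_mismatch_rejected(self):
        table = _labeled(400)
        clf = ml.train_classifier(table, seed=1)
        with pytest.raises(SchemaError):
            ml.predict_inducibility(clf, {"m_gK1": 1.5})

    def test_size_sensitive_fixture_prefers_dilated(self):
        rule = sd.GeneratorRule(
            ((sd.RuleClause("tissue_area", 18.0, "gt"),
              sd.RuleClause("m_gK1", 1.0, "gt")),), noise=0.0)
        table = sd.gen_outcome_table(1500, rule, seed=2)
        clf = ml.train_classifier(table, seed=2)
        base = {n: 1.2 for n in MULTIPLIER_NAMES}
        small = dict(base, tissue_area=16.0)
        big = dict(base, tissue_area=20.25)
        _, p_small = ml.predict_inducibility(clf, small)
        _, p_big = ml.predict_inducibility(clf, big)
        assert p_big >= p_small


class TestDecisionPaths:
    def test_single_feature_rule_depth_one(self):
        rule = sd.single_feature_rule("m_gNa", 1.3)
        table = sd.gen_outcome_table(500, rule, seed=4)
        summary = ml.extract_decision_paths(table, max_depth=7)
        assert summary.root_feature == "m_gNa"
        assert all(p.depth == 1 for p in summary.paths)

    def test_threshold_recovery(self):
        table = _labeled(2000, seed=9, noise=0.0)
        summary = ml.extract_decision_paths(table, max_depth=7)
        assert summary.root_feature == "m_gK1"
        assert summary.root_threshold == pytest.approx(1.09, abs=0.05)

    def test_depth_bound_respected(self):
        table = sd.gen_outcome_table(2000, "paper_clusters", seed=1, noise=0.02)
        summary = ml.extract_decision_paths(table, max_depth=7)
        assert max(p.depth for p in summary.paths) <= 7

    def test_cluster_archetypes_among_induced_leaves(self):
        table = sd.gen_outcome_table(2000, "paper_clusters", seed=1, noise=0.0)
        summary = ml.extract_decision_paths(table, max_depth=7)
        recovered = ml.archetypes_recovered(summary, table,
                                            sd.PAPER_CLUSTERS_RULE)
        assert recovered == [True, True]

    def test_sunburst_structure(self):
        table = _labeled(500)
        summary = ml.extract_decision_paths(table, max_depth=3)
        node = summary.sunburst
        assert node["name"] == summary.root_feature
        assert len(node["children"]) == 2

        def leaves(n):
            if "children" not in n:
                yield n
            else:
                for c in n["children"]:
                    yield from leaves(c)

        labels = {leaf["label"] for leaf in leaves(node)}
        assert labels <= {"induced", "non_inducible"}
        assert len(labels) == 2
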