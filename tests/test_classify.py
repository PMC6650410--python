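"""SVM age model: features, training, scoring geometry, panel reduction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

import pepage as pp
from pepage.classify import _cv_accuracy, take_one_out_optimize
from pepage.errors import AnalysisError, ConfigurationError

from _oracles import dual_form_decision

HYPER = pp.SvmHyperparameters()  # C=3.2, gamma=0.008


def _matrix(amps, samples, ids=None):
    ids = ids if ids is not None else list(range(1, len(amps) + 1))
    peptides = pd.DataFrame(
        {"mass_da": [1000.0 * i for i in ids], "migration_min": [20.0 + i for i in ids]},
        index=pd.Index(ids, name="master_id"),
    )
    return pp.MatchedMatrix(
        peptides=peptides,
        amplitudes=pd.DataFrame(np.asarray(amps, dtype=float),
                                index=peptides.index, columns=samples),
    )


class TestPrepareFeatures:
    def test_missing_and_zero_amplitudes_map_to_zero_feature(self):
        mat = _matrix([[np.nan, 0.0], [1.0, 3.0]], ["s1", "s2"])
        feats = pp.prepare_features(mat, [1, 2])
        assert feats.loc["s1", 1] == 0.0
        assert feats.loc["s2", 1] == 0.0
        assert feats.loc["s1", 2] == 1.0  # log2(1+1)
        assert feats.loc["s2", 2] == 2.0  # log2(1+3)

    def test_column_order_follows_panel(self):
        mat = _matrix([[1.0, 2.0], [3.0, 4.0]], ["s1", "s2"])
        assert list(pp.prepare_features(mat, [2, 1]).columns) == [2, 1]

    def test_features_survive_matrix_roundtrip(self, tmp_path):
        mat = _matrix([[1.5, np.nan, 2.5], [0.0, 7.0, 8.0]], ["s1", "s2", "s3"])
        pp.write_matched_matrix(mat, tmp_path / "m.tsv")
        back = pp.read_matched_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(
            pp.prepare_features(mat, [1, 2]), pp.prepare_features(back, [1, 2])
        )

    def test_absent_panel_peptide_listed(self):
        mat = _matrix([[1.0, 2.0]], ["s1", "s2"])
        with pytest.raises(AnalysisError, match=r"\[9\]"):
            pp.prepare_features(mat, [9])


class TestTrainAndScore:
    def test_two_point_toy_is_symmetric(self):
        feats = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], columns=[1, 2], index=["a", "b"])
        model = pp.train_svm(feats, ["young", "old"],
                             pp.SvmHyperparameters(C=3.2, gamma=0.5),
                             positive_label="old")
        s = model.scores(feats.to_numpy())
        assert len(model.support_vectors) == 2
        assert s[0] == pytest.approx(-s[1])
        assert s[1] > 0  # 'old' is the positive pole
        mid = pp.classification_score(model, np.array([0.5, 0.5]))
        assert mid == pytest.approx(0.0, abs=1e-9)

    def test_xor_pattern_separable_with_rbf(self):
        feats = pd.DataFrame([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]],
                             columns=[1, 2], index=list("abcd"))
        labels = ["young", "young", "old", "old"]
        model = pp.train_svm(feats, labels, pp.SvmHyperparameters(C=10.0, gamma=1.0),
                             positive_label="old")
        pred = np.sign(model.decision_values(feats.to_numpy()))
        assert list(pred) == [-1, -1, 1, 1]

    def test_unbounded_support_vector_sits_on_margin(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        feats = pd.DataFrame(x, columns=[1, 2], index=[f"s{i}" for i in range(20)])
        labels = ["young"] * 10 + ["old"] * 10
        hyper = pp.SvmHyperparameters(C=3.2, gamma=0.3)
        model = pp.train_svm(feats, labels, hyper, positive_label="old")
        dec = model.decision_values(model.support_vectors)
        unbounded = np.abs(model.dual_coef) < hyper.C - 1e-8
        assert unbounded.any()
        # KKT: unbounded SVs have |decision| = 1, i.e. |score| = 1/||w||
        # (within the solver's convergence tolerance)
        assert np.allclose(np.abs(dec[unbounded]), 1.0, atol=5e-3)
        scores = model.scores(model.support_vectors)
        assert np.allclose(
            np.abs(scores[unbounded]), 1.0 / model.w_norm, atol=5e-3 / model.w_norm
        )

    def test_score_equals_explicit_dual_sum(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(2, 1, (8, 3))])
        feats = pd.DataFrame(x, columns=[1, 2, 3], index=[f"s{i}" for i in range(16)])
        model = pp.train_svm(feats, ["young"] * 8 + ["old"] * 8,
                             pp.SvmHyperparameters(C=3.2, gamma=0.1),
                             positive_label="old")
        probe = rng.normal(0, 2, (20, 3))
        ours = model.decision_values(probe)
        oracle = dual_form_decision(model, probe)
        assert np.allclose(ours, oracle, atol=1e-8)
        # and against sklearn's own decision function
        clf = SVC(C=3.2, gamma=0.1, kernel="rbf")
        idx = np.argsort(feats.index.to_numpy())
        clf.fit(x[idx], np.where(np.array(["young"] * 8 + ["old"] * 8)[idx] == "old", 1, -1))
        assert np.allclose(ours, clf.decision_function(probe), atol=1e-8)

    def test_single_class_rejected(self):
        feats = pd.DataFrame([[0.0], [1.0]], columns=[1], index=["a", "b"])
        with pytest.raises(AnalysisError):
            pp.train_svm(feats, ["young", "young"])

    def test_dimension_mismatch_rejected(self):
        feats = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], columns=[1, 2], index=["a", "b"])
        model = pp.train_svm(feats, ["young", "old"], HYPER)
        with pytest.raises(AnalysisError):
            pp.classification_score(model, np.array([1.0]))

    def test_model_json_roundtrip_scores_identically(self, tmp_path):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(2, 1, (6, 2))])
        feats = pd.DataFrame(x, columns=[1, 2], index=[f"s{i}" for i in range(12)])
        model = pp.train_svm(feats, ["young"] * 6 + ["old"] * 6, HYPER)
        model.save(tmp_path / "model.json")
        back = pp.AgeScoreModel.load(tmp_path / "model.json")
        probe = rng.normal(0, 1, (5, 2))
        assert np.array_equal(model.scores(probe), back.scores(probe))

    def test_training_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(2, 1, (6, 2))])
        feats = pd.DataFrame(x, columns=[1, 2], index=[f"s{i:02d}" for i in range(12)])
        labels = pd.Series(["young"] * 6 + ["old"] * 6, index=feats.index)
        m1 = pp.train_svm(feats, labels, HYPER)
        perm = feats.sample(frac=1.0, random_state=4)
        m2 = pp.train_svm(perm, labels.loc[perm.index], HYPER)
        assert np.array_equal(m1.support_vectors, m2.support_vectors)
        assert np.array_equal(m1.dual_coef, m2.dual_coef)
        assert m1.intercept == m2.intercept


class TestTakeOneOut:
    def _separated(self, seed, n=13, informative=5, noise=9):
        rng = np.random.default_rng(seed)
        xa = np.column_stack([rng.normal(3, 1, n), rng.normal(0, 1, n)])
        xb = np.column_stack([rng.normal(9, 1, n), rng.normal(0, 1, n)])
        feats = pd.DataFrame(np.vstack([xa, xb]), columns=[informative, noise],
                             index=[f"S{i:03d}" for i in range(2 * n)])
        return feats, ["young"] * n + ["old"] * n

    def test_noise_peptide_eliminated(self):
        removed = 0
        for seed in range(20):
            feats, labels = self._separated(seed)
            model = take_one_out_optimize(
                feats, labels, hyper=pp.SvmHyperparameters(C=3.2, gamma=0.1)
            )
            removed += model.panel == [5]
        assert removed >= 18

    def test_redundant_copies_are_pruned_without_cv_change(self):
        rng = np.random.default_rng(0)
        col = np.concatenate([rng.normal(0, 1, 8), rng.normal(4, 1, 8)])
        feats = pd.DataFrame(
            np.column_stack([col, col, col]), columns=[1, 2, 3],
            index=[f"s{i:02d}" for i in range(16)],
        )
        labels = ["young"] * 8 + ["old"] * 8
        hyper = pp.SvmHyperparameters(C=3.2, gamma=0.2)
        base = _cv_accuracy(feats.to_numpy(), np.array([-1] * 8 + [1] * 8), hyper)
        model = take_one_out_optimize(feats, labels, hyper=hyper)
        assert len(model.panel) < 3  # at least one identical copy dropped
        final = _cv_accuracy(
            feats.loc[:, model.panel].to_numpy(), np.array([-1] * 8 + [1] * 8), hyper
        )
        assert final >= base  # reduction never costs CV accuracy

    def test_panel_kept_when_both_drops_hurt(self):
        # XOR: either coordinate alone is uninformative, both are needed
        rng = np.random.default_rng(1)
        base = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        x = np.vstack([base + rng.normal(0, 0.05, (4, 2)) for _ in range(6)])
        labels = (["young", "young", "old", "old"]) * 6
        feats = pd.DataFrame(x, columns=[1, 2], index=[f"s{i:02d}" for i in range(24)])
        model = take_one_out_optimize(
            feats, labels, hyper=pp.SvmHyperparameters(C=10.0, gamma=2.0), cv=4
        )
        assert model.panel == [1, 2]

    def test_excessive_folds_rejected(self):
        feats, labels = self._separated(0, n=4)
        with pytest.raises(ConfigurationError):
            take_one_out_optimize(feats, labels, cv=10,
                                  hyper=pp.SvmHyperparameters(C=3.2, gamma=0.1))


class TestScoreCohort:
    def test_training_samples_score_on_their_side(self, matched_default_cohort):
        config, mat, design, truth = matched_default_cohort
        mapping = pp.match_truth_to_matrix(truth, mat)
        panel = sorted(mapping[i] for i in truth.affected_ids if i in mapping)
        model = pp.fit_age_model(mat, design, panel)
        scores = pp.score_cohort(model, mat, design)
        young = scores[scores.age_group == "young"]["score"]
        old = scores[scores.age_group == "old"]["score"]
        assert (young < 0).mean() >= 0.9
        assert (old > 0).mean() >= 0.9

    def test_middle_age_scores_between_extremes(self, matched_default_cohort):
        config, mat, design, truth = matched_default_cohort
        mapping = pp.match_truth_to_matrix(truth, mat)
        panel = sorted(mapping[i] for i in truth.affected_ids if i in mapping)
        model = pp.fit_age_model(mat, design, panel)
        g = pp.score_cohort(model, mat, design).groupby("age_group")["score"].mean()
        assert g["young"] < g["middle"] < g["old"]

    def test_young_like_treated_old_scores_below_untreated_old(self):
        config = pp.SimulationConfig(
            treatments=("control", "apelin"), treatment_age_shift=-2.0, seed=21
        )
        profiles, design, truth = pp.generate_cohort(config)
        ref = pp.reference_standards(config)
        mat = pp.match_profiles(pp.normalize_cohort(profiles, ref), reference=ref)
        mapping = pp.match_truth_to_matrix(truth, mat)
        panel = sorted(mapping[i] for i in truth.affected_ids if i in mapping)
        model = pp.fit_age_model(mat, design, panel, treatment="control")
        scores = pp.score_cohort(model, mat, design)
        old = scores[scores.age_group == "old"]
        assert (
            old[old.treatment == "apelin"]["score"].mean()
            < old[old.treatment == "control"]["score"].mean()
        )
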