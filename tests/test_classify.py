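import itertools

import numpy as np
import pandas as pd
import pytest

from mesa_cfdna.classify import (ModelConfig, auc_mann_whitney, cross_cohort,
                                 derive_seed, evaluate, evaluate_multiclass,
                                 fit_modality_model, fit_stacked,
                                 inner_cv_base_predictions, loocv_multimodal,
                                 loocv_single_modality,
                                 probability_correlations,
                                 sensitivity_at_specificity)
from mesa_cfdna.errors import UsageError, ValidationError
from mesa_cfdna.features import FeatureMatrix

FAST = ModelConfig(trees=20)


def brute_force_auc(probs, labels, pos="cancer"):
    """Concordant-pair counting with half-credit ties."""
    cases = [p for p, l in zip(probs, labels) if l == pos]
    controls = [p for p, l in zip(probs, labels) if l != pos]
    total = 0.0
    for a, b in itertools.product(cases, controls):
        total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(cases) * len(controls))


def make_fm(values, labels, modality="occupancy"):
    values = pd.DataFrame(values, dtype=float)
    values.index = [f"s{i}" for i in range(len(values))]
    return FeatureMatrix(values, pd.Series(modality, index=values.columns),
                         pd.Series(labels, index=values.index))


def signal_cohort(rng, n=24, n_feats=8, shift=3.0, modality="occupancy"):
    labels = ["cancer", "control"] * (n // 2)
    X = rng.normal(size=(n, n_feats))
    X[np.array(labels) == "cancer", :2] += shift
    return make_fm(X, labels, modality)


class TestEvaluate:
    def test_perfect_separation(self):
        probs = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("abcd"))
        labels = pd.Series(["cancer", "cancer", "control", "control"],
                           index=list("abcd"))
        rep = evaluate(probs, labels)
        assert rep.auc == 1.0
        assert rep.sensitivity_at_spec == 1.0
        assert rep.f1 == 1.0
        assert rep.confusion.to_numpy().tolist() == [[2, 0], [0, 2]]

    def test_three_of_four_concordant_pairs(self):
        probs = pd.Series([0.6, 0.4, 0.5, 0.3], index=list("abcd"))
        labels = pd.Series(["cancer", "cancer", "control", "control"],
                           index=list("abcd"))
        assert evaluate(probs, labels).auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        probs = pd.Series([0.5] * 6, index=list("abcdef"))
        labels = pd.Series(["cancer"] * 3 + ["control"] * 3,
                           index=list("abcdef"))
        assert evaluate(probs, labels).auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(10, 200))
            labels = ["cancer" if v else "control"
                      for v in rng.integers(0, 2, size=n)]
            if len(set(labels)) < 2:
                continue
            probs = np.round(rng.uniform(size=n), 2)  # rounding induces ties
            idx = [f"s{i}" for i in range(n)]
            got = evaluate(pd.Series(probs, index=idx),
                           pd.Series(labels, index=idx)).auc
            assert got == pytest.approx(brute_force_auc(probs, labels),
                                        abs=1e-12)

    def test_sensitivity_at_specificity_hand_case(self):
        # controls 0.1..0.8; threshold reaching 90% specificity is above
        # 9 of 10 controls; cases >= that threshold: 2 of 3
        controls = [0.05 * i for i in range(1, 11)]
        cases = [0.9, 0.55, 0.2]
        probs = pd.Series(cases + controls)
        labels = pd.Series(["cancer"] * 3 + ["control"] * 10)
        got = sensitivity_at_specificity(probs, labels, "cancer", 0.90)
        assert got == pytest.approx(2 / 3)

    def test_one_class_absent_rejected(self):
        probs = pd.Series([0.4, 0.6])
        labels = pd.Series(["cancer", "cancer"])
        with pytest.raises(ValidationError):
            evaluate(probs, labels)


class TestEvaluateMulticlass:
    def test_perfect_one_hot(self):
        probs = pd.DataFrame([[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                             columns=["a", "b", "c"], dtype=float)
        labels = pd.Series(["a", "b", "c"])
        rep = evaluate_multiclass(probs, labels)
        assert rep.accuracy == 1.0
        assert np.trace(rep.confusion.to_numpy()) == 3

    def test_uniform_probabilities_tie_break_first_class(self):
        probs = pd.DataFrame(np.full((6, 3), 1 / 3), columns=["b", "a", "c"])
        labels = pd.Series(["a", "a", "b", "b", "c", "c"])
        rep = evaluate_multiclass(probs, labels)
        # every argmax tie resolves to class 'a'
        assert rep.accuracy == pytest.approx(2 / 6)
        assert rep.confusion["a"].sum() == 6

    def test_confusion_matches_hand_count(self):
        probs = pd.DataFrame(
            [[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.3, 0.5],
             [0.5, 0.4, 0.1], [0.1, 0.6, 0.3], [0.3, 0.3, 0.4]],
            columns=["a", "b", "c"])
        labels = pd.Series(["a", "b", "c", "b", "b", "a"])
        rep = evaluate_multiclass(probs, labels)
        assert rep.accuracy == pytest.approx(4 / 6)
        assert rep.confusion.loc["b", "a"] == 1   # sample 3 misassigned
        assert rep.confusion.loc["a", "c"] == 1   # sample 5 misassigned

    def test_unknown_label_rejected(self):
        probs = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"])
        with pytest.raises(ValidationError):
            evaluate_multiclass(probs, pd.Series(["z"]))


class TestProbabilityCorrelations:
    def test_identical_and_reversed(self):
        base = np.arange(10) / 10
        df = pd.DataFrame({"m1": base, "m2": base, "m3": base[::-1]})
        corr = probability_correlations(df)
        assert corr.loc["m1", "m2"] == pytest.approx(1.0)
        assert corr.loc["m1", "m3"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_constant_vector_pair_missing(self):
        df = pd.DataFrame({"m1": np.arange(5.0), "m2": np.ones(5)})
        corr = probability_correlations(df)
        assert np.isnan(corr.loc["m1", "m2"])

    def test_independent_vectors_weakly_correlated(self, rng):
        hits = 0
        for _ in range(20):
            df = pd.DataFrame(rng.uniform(size=(100, 2)), columns=["a", "b"])
            if abs(probability_correlations(df).loc["a", "b"]) < 0.3:
                hits += 1
        assert hits >= 19


class TestLoocvSingleModality:
    def test_label_copy_feature_gives_auc_one(self, rng):
        labels = ["cancer", "control"] * 20
        X = pd.DataFrame({"copy": [1.0 if l == "cancer" else 0.0 for l in labels],
                          "noise": rng.normal(size=40)})
        fm = make_fm(X, labels)
        _, rep = loocv_single_modality(fm, FAST, seed=0)
        assert rep.auc == 1.0

    def test_permuted_labels_near_half(self, rng):
        # LOOCV under the null is pessimistically biased (the training
        # complement under-represents the held-out class), so the band is
        # asymmetric-tolerant rather than tight around 0.5
        aucs = []
        for rep_i in range(6):
            labels = list(rng.permutation(["cancer", "control"] * 20))
            fm = make_fm(rng.normal(size=(40, 6)), labels)
            try:
                _, rep = loocv_single_modality(fm, ModelConfig(trees=15),
                                               seed=rep_i)
            except ValidationError:
                continue
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_too_few_samples_rejected(self, rng):
        fm = make_fm(rng.normal(size=(6, 3)), ["cancer", "control"] * 3)
        with pytest.raises(UsageError):
            loocv_single_modality(fm, FAST, seed=0)


class TestInnerCv:
    def test_every_sample_gets_one_oof_probability(self, rng):
        fms = {"occupancy": signal_cohort(rng, n=40),
               "wps": signal_cohort(rng, n=40, modality="wps")}
        oof = inner_cv_base_predictions(fms, FAST, seed=1)
        assert oof.shape == (40, 4)  # 2 modalities x 2 classes
        assert not oof.isna().any().any()
        np.testing.assert_allclose(
            oof[["occupancy|cancer", "occupancy|control"]].sum(axis=1), 1.0)

    def test_deterministic_given_seed(self, rng):
        fms = {"occupancy": signal_cohort(rng, n=20)}
        a = inner_cv_base_predictions(fms, FAST, seed=9)
        b = inner_cv_base_predictions(fms, FAST, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_k_equal_n_per_class_reduces_to_loocv_granularity(self, rng):
        fm = signal_cohort(rng, n=20)
        oof = inner_cv_base_predictions({"occupancy": fm},
                                        FAST.replace(inner_k=20), seed=2)
        assert len(oof) == 20


class TestStacking:
    def _oof(self, rng, n=200, flip=0.15):
        y = np.array(["cancer", "control"] * (n // 2))
        cols = {}
        for name in ("m1", "m2"):
            flipped = rng.uniform(size=n) < flip
            p = np.where((y == "cancer") ^ flipped,
                         rng.uniform(0.55, 1.0, n), rng.uniform(0.0, 0.45, n))
            cols[f"{name}|cancer"] = p
            cols[f"{name}|control"] = 1 - p
        idx = [f"s{i}" for i in range(n)]
        return (pd.DataFrame(cols, index=idx),
                pd.Series(y, index=idx))

    def test_monotone_in_single_shared_probability(self, rng):
        oof, y = self._oof(rng)
        # all modalities identical -> meta must be monotone in that input
        oof[["m2|cancer", "m2|control"]] = oof[["m1|cancer", "m1|control"]].to_numpy()
        meta = fit_stacked(oof, y, FAST, seed=0)
        grid = np.linspace(0, 1, 21)
        X = np.column_stack([grid, 1 - grid, grid, 1 - grid])
        p = meta.predict_proba(X)[:, list(meta.classes_).index("cancer")]
        assert (np.diff(p) >= -1e-12).all()

    def test_complementary_columns_beat_each_single(self, rng):
        oof, y = self._oof(rng, n=400, flip=0.2)
        half = 200
        meta = fit_stacked(oof.iloc[:half], y.iloc[:half], FAST, seed=0)
        test = oof.iloc[half:]
        stacked = pd.Series(
            meta.predict_proba(test.to_numpy())[:, list(meta.classes_).index("cancer")],
            index=test.index)
        stacked_auc = evaluate(stacked, y).auc
        for col in ("m1|cancer", "m2|cancer"):
            assert stacked_auc > evaluate(test[col], y).auc

    def test_missing_base_column_rejected(self, rng):
        oof, y = self._oof(rng, n=20)
        oof.iloc[3, 0] = np.nan
        with pytest.raises(Exception):
            fit_stacked(oof, y, FAST, seed=0)


class TestLeakageGuard:
    def test_held_out_mutation_changes_nothing_trained(self, rng):
        fm = signal_cohort(rng, n=20)
        mutated = FeatureMatrix(fm.values.copy(), fm.modality.copy(),
                                fm.labels.copy())
        mutated.values.iloc[0, :] = 999.0   # corrupt the held-out sample
        train = fm.sample_ids[1:]
        probe = pd.DataFrame(rng.normal(size=(3, fm.values.shape[1])),
                             columns=fm.values.columns)
        m1 = fit_modality_model(fm, train, FAST, seed=4)
        m2 = fit_modality_model(mutated, train, FAST, seed=4)
        assert m1.features == m2.features
        np.testing.assert_array_equal(m1.predict_proba(probe),
                                      m2.predict_proba(probe))

    def test_inner_cv_ignores_out_of_training_rows(self, rng):
        fm = signal_cohort(rng, n=22)
        mutated = FeatureMatrix(fm.values.copy(), fm.modality.copy(),
                                fm.labels.copy())
        mutated.values.iloc[20:, :] = -555.0
        train = fm.sample_ids[:20]
        a = inner_cv_base_predictions({"occupancy": fm.subset_samples(train)},
                                      FAST, seed=3)
        b = inner_cv_base_predictions(
            {"occupancy": mutated.subset_samples(train)}, FAST, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestMultimodalLoocv:
    def test_smoke_cohort_emits_one_probability_per_sample(self, rng):
        fms = {"occupancy": signal_cohort(rng, n=12),
               "methylation": signal_cohort(rng, n=12, modality="methylation")}
        res = loocv_multimodal(fms, ModelConfig(trees=10), seed=0)
        assert len(res.final_probs) == 12
        assert res.final_probs.index.tolist() == fms["occupancy"].sample_ids
        assert ((res.final_probs >= 0) & (res.final_probs <= 1)).all()
        assert res.base_probs.shape == (12, 2)

    def test_concordant_signal_not_hurt_by_stacking(self, rng):
        fms = {"occupancy": signal_cohort(rng, n=30, shift=2.5),
               "wps": signal_cohort(rng, n=30, shift=2.5, modality="wps")}
        res = loocv_multimodal(fms, ModelConfig(trees=25), seed=1)
        best_single = max(r.auc for r in res.base_reports.values())
        assert res.report.auc >= best_single - 0.05

    def test_three_class_mode_reports_accuracy(self, rng):
        labels = ["hcc", "pdac", "control"] * 8
        X = rng.normal(size=(24, 6))
        for j, lab in enumerate(("hcc", "pdac", "control")):
            X[np.array(labels) == lab, j] += 3.0
        fms = {"occupancy": make_fm(X, labels)}
        res = loocv_multimodal(fms, ModelConfig(trees=25), seed=0)
        assert res.report.accuracy is not None
        assert res.report.accuracy > 0.6
        assert res.report.confusion.to_numpy().sum() == 24


class TestCrossCohort:
    def test_shared_effect_transfers(self, rng):
        train = signal_cohort(rng, n=40, shift=3.0)
        test = signal_cohort(rng, n=30, shift=3.0)
        probs, rep = cross_cohort({"occupancy": train}, {"occupancy": test},
                                  ModelConfig(trees=30), seed=0)
        assert rep.auc >= 0.85
        assert probs.index.tolist() == test.sample_ids

    def test_resubstitution_upper_bound(self, rng):
        fm = signal_cohort(rng, n=30, shift=2.0)
        _, loocv_rep = loocv_single_modality(fm, ModelConfig(trees=30), seed=1)
        _, resub_rep = cross_cohort({"occupancy": fm}, {"occupancy": fm},
                                    ModelConfig(trees=30), seed=1)
        assert resub_rep.auc >= loocv_rep.auc - 1e-9

    def test_permuted_test_labels_near_half(self, rng):
        train = signal_cohort(rng, n=40, shift=3.0)
        test = signal_cohort(rng, n=40, shift=0.0)  # no class difference
        _, rep = cross_cohort({"occupancy": train}, {"occupancy": test},
                              ModelConfig(trees=30), seed=2)
        assert abs(rep.auc - 0.5) < 0.25

    def test_disjoint_feature_universes_rejected(self, rng):
        train = signal_cohort(rng, n=20)
        test = signal_cohort(rng, n=20)
        test.values.columns = [f"other{i}" for i in range(test.values.shape[1])]
        test = FeatureMatrix(test.values,
                             pd.Series("occupancy", index=test.values.columns),
                             test.labels)
        with pytest.raises(Exception, match="shared"):
            cross_cohort({"occupancy": train}, {"occupancy": test},
                         FAST, seed=0)


class TestFixedFeatures:
    def test_selection_bypassed_and_models_use_exactly_the_list(self, rng):
        fm = signal_cohort(rng, n=20)
        wanted = tuple(fm.feature_ids[:3])
        cfg = FAST.replace(fixed_features=wanted)
        model = fit_modality_model(fm, fm.sample_ids[1:], cfg, seed=0)
        assert sorted(model.features) == sorted(wanted)

    def test_no_overlap_with_matrix_rejected(self, rng):
        fm = signal_cohort(rng, n=20)
        cfg = FAST.replace(fixed_features=("nope",))
        with pytest.raises(Exception, match="fixed features"):
            fit_modality_model(fm, fm.sample_ids[1:], cfg, seed=0)


def test_derive_seed_stable_and_bounded():
    assert derive_seed(7, 1, 2) == derive_seed(7, 1, 2)
    assert derive_seed(7, 1) != derive_seed(7, 2)
    for s in (0, 1, 2**31 - 1):
        assert 0 <= derive_seed(s, 5, 5) < 2**31
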