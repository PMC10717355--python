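"""Burden features, clinical screening, boosted models and DeLong machinery."""

import numpy as np
import pandas as pd
import pytest

from sgaburden.prognosis import (
    GbmConfig,
    auc_ci_delong,
    burden_features,
    delong_paired_test,
    evaluate_two_models,
    select_clinical_factors,
    split_train_test,
    train_gbm,
)
from sgaburden.simulate import scenario_prognosis, simulate_cohort
from sgaburden.variants import GeneTypeCountMatrix, VariantType


def _matrix(ptv_rows, mis_rows, syn_rows, samples):
    counts = {vt: np.zeros((len(ptv_rows), len(samples)), dtype=np.int32) for vt in VariantType}
    counts[VariantType.PTV][:] = ptv_rows
    counts[VariantType.MIS][:] = mis_rows
    counts[VariantType.SYN][:] = syn_rows
    return GeneTypeCountMatrix([f"G{i}" for i in range(len(ptv_rows))], samples, counts)


class TestBurdenFeatures:
    def test_severity_scoring(self):
        samples = ["ptv_only", "mis_only", "syn_only", "ptv_and_mis", "nothing"]
        mat = _matrix(
            ptv_rows=[[1, 0, 0, 2, 0]],
            mis_rows=[[0, 1, 0, 1, 0]],
            syn_rows=[[0, 0, 3, 0, 0]],
            samples=samples,
        )
        feats = burden_features(mat, ["G0"])
        assert feats["burden_G0"].tolist() == [2, 1, 0, 2, 0]

    def test_values_stay_in_012(self, small_matrix):
        feats = burden_features(small_matrix, small_matrix.genes[:5])
        assert set(np.unique(feats.to_numpy())) <= {0, 1, 2}

    def test_sum_mode(self):
        samples = ["a", "b"]
        mat = _matrix([[1, 0], [0, 0]], [[0, 1], [1, 1]], [[0, 0], [0, 0]], samples)
        feats = burden_features(mat, ["G0", "G1"], mode="sum")
        # sample a: PTV in G0 (2) + MIS in G1 (1); sample b: MIS in both (1+1)
        assert feats["burden_sum"].tolist() == [3, 2]

    def test_unknown_gene_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            burden_features(small_matrix, ["NOT_A_GENE"])


class TestClinicalScreen:
    def _cohort(self, seed=0, n=600, strong=("neurologic",), n_flags=4):
        rng = np.random.default_rng(seed)
        flags = {f"flag{i}": rng.random(n) < 0.3 for i in range(n_flags)}
        flags.update({name: rng.random(n) < 0.3 for name in strong})
        logit = -2.0 + sum(np.log(3.0) * flags[name] for name in strong)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame({**flags, "poor_prognosis": y})

    def test_planted_factor_selected(self):
        hits = 0
        for seed in range(10):
            df = self._cohort(seed=seed)
            sel = select_clinical_factors(
                df, candidates=[c for c in df.columns if c != "poor_prognosis"]
            )
            hits += "neurologic" in sel
        assert hits >= 9

    def test_null_factor_rarely_selected(self):
        hits = 0
        for seed in range(20):
            df = self._cohort(seed=seed + 100)
            sel = select_clinical_factors(
                df, candidates=[c for c in df.columns if c != "poor_prognosis"]
            )
            hits += "flag0" in sel
        assert hits <= 4  # ~5% type-I rate

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"flag0": [True, False], "poor_prognosis": [False, False]})
        with pytest.raises(ValueError):
            select_clinical_factors(df, candidates=["flag0"])


class TestSplit:
    def _df(self, n=100, prevalence=0.1, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"sample_id": range(n), "poor_prognosis": rng.random(n) < prevalence}
        )

    def test_disjoint_exhaustive(self):
        df = self._df()
        train, test = split_train_test(df, seed=1)
        assert len(train) == 70 and len(test) == 30
        assert not set(train["sample_id"]) & set(test["sample_id"])

    def test_same_seed_same_split(self):
        df = self._df()
        a, _ = split_train_test(df, seed=2)
        b, _ = split_train_test(df, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_stratification_keeps_both_classes(self):
        df = self._df(n=200, prevalence=0.1, seed=3)
        train, test = split_train_test(df, seed=3)
        assert train["poor_prognosis"].any() and test["poor_prognosis"].any()


class TestTrainGbm:
    _fast = GbmConfig(cv_folds=3, cv_repeats=1, grid={"n_estimators": [20], "max_depth": [1]})

    def test_separable_feature_perfect_training_auc(self):
        y = np.array([0] * 30 + [1] * 30)
        X = pd.DataFrame({"x": y.astype(float)})
        model = train_gbm(X, y, self._fast)
        scores = model.predict_proba(X.to_numpy())[:, 1]
        assert auc_ci_delong(y, scores)[0] == 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.normal(size=80)})
        y = (X["a"] + rng.normal(size=80) > 0).astype(int)
        m1 = train_gbm(X, y, self._fast)
        m2 = train_gbm(X, y, self._fast)
        np.testing.assert_array_equal(
            m1.predict_proba(X.to_numpy()), m2.predict_proba(X.to_numpy())
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_gbm(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1], self._fast)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            train_gbm(
                pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}),
                [0, 1, 0, 1],
                GbmConfig(grid={}),
            )


def auc_pair_counting(labels, scores):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked concordantly."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDelong:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([0, 1], [0.1, 0.9], 1.0),
            ([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5], 0.5),
            ([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8], 0.75),
        ],
    )
    def test_auc_examples(self, labels, scores, expected):
        auc, (lo, hi) = auc_ci_delong(labels, scores)
        assert auc == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_auc_matches_pair_counting(self):
        rng = np.random.default_rng(7)
        for n in (20, 75, 200):
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.normal(size=n) + y
            s[rng.random(n) < 0.2] = 0.5  # inject ties
            auc, _ = auc_ci_delong(y, s)
            assert auc == pytest.approx(auc_pair_counting(y, s), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 60)
        y[:5] = 1
        y[5:10] = 0
        s = rng.normal(size=60)
        a1, ci1 = auc_ci_delong(y, s)
        a2, ci2 = auc_ci_delong(y, np.exp(3 * s))
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert ci1 == pytest.approx(ci2, abs=1e-9)

    def test_ci_and_paired_p_match_reference_implementation(self):
        """Frozen cross-check against an independent DeLong implementation
        (R pROC 1.19: ci.auc and paired roc.test on this exact fixture)."""
        rng = np.random.default_rng(42)
        n = 40
        y = rng.integers(0, 2, n)
        s1 = y * 0.8 + rng.normal(0, 1, n)
        s2 = y * 0.3 + rng.normal(0, 1, n)
        auc1, ci1 = auc_ci_delong(y, s1)
        assert ci1 == pytest.approx((0.7144, 0.9582), abs=5e-4)
        assert delong_paired_test(y, s1, s2) == pytest.approx(0.01333687, abs=1e-6)

    def test_identical_scores_give_p_one(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.2, 0.8, 0.3, 0.7, 0.9, 0.1]
        assert delong_paired_test(y, s, s) == 1.0

    def test_order_symmetric(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s1, s2 = rng.normal(size=50), rng.normal(size=50)
        assert delong_paired_test(y, s1, s2) == pytest.approx(
            delong_paired_test(y, s2, s1), rel=1e-12
        )

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(10)
        n = 500
        y = rng.integers(0, 2, n)
        y[:10] = 1
        y[10:20] = 0
        perfect = y.astype(float)
        noise = rng.normal(size=n)
        assert delong_paired_test(y, perfect, noise) < 0.001

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            delong_paired_test([0, 1], [0.1, 0.9], [0.1, 0.9, 0.5])


class TestEvaluateTwoModels:
    _fast = GbmConfig(cv_folds=3, cv_repeats=1, grid={"n_estimators": [30], "max_depth": [1]})

    def _datasets(self, seed=0):
        rng = np.random.default_rng(seed)

        def make(n):
            df = pd.DataFrame(
                {
                    "clin": rng.random(n) < 0.3,
                    "gene1": rng.integers(0, 3, n),
                }
            )
            logit = -2.0 + 1.0 * df["clin"] + 1.2 * df["gene1"]
            df["poor_prognosis"] = rng.random(n) < 1 / (1 + np.exp(-logit))
            return df

        return make(200), make(100), make(80)

    def test_four_evaluations_with_paired_p(self):
        train, test, val = self._datasets()
        evals, _ = evaluate_two_models(train, test, val, ["clin"], ["gene1"], config=self._fast)
        assert {(e.model_id, e.dataset_id) for e in evals} == {
            ("clinical", "test"),
            ("clinical_genetic", "test"),
            ("clinical", "validation"),
            ("clinical_genetic", "validation"),
        }
        for e in evals:
            assert 0.0 <= e.ci_low <= e.auc <= e.ci_high <= 1.0
            assert 0.0 <= e.paired_p <= 1.0

    def test_missing_feature_column_is_hard_error(self):
        train, test, val = self._datasets()
        with pytest.raises(KeyError, match="gene1"):
            evaluate_two_models(train, test.drop(columns="gene1"), None, ["clin"], ["gene1"], config=self._fast)

    def test_validation_labels_do_not_affect_predictions(self):
        """Leakage guard: the frozen pipeline scores validation samples
        identically whatever their labels are."""
        train, test, val = self._datasets(seed=3)
        _, art1 = evaluate_two_models(train, test, val, ["clin"], ["gene1"], config=self._fast)
        shuffled = val.copy()
        shuffled["poor_prognosis"] = (
            shuffled["poor_prognosis"].sample(frac=1, random_state=0).to_numpy()
        )
        _, art2 = evaluate_two_models(train, test, shuffled, ["clin"], ["gene1"], config=self._fast)
        for key in art1["scores"]:
            np.testing.assert_array_equal(art1["scores"][key], art2["scores"][key])


def test_genetic_signal_improves_heldout_auc():
    """On the canonical prognosis scenario, adding burden features beats the
    clinical-only model out of sample (single-seed smoke; the multi-seed rate
    is exercised in the acceptance suite)."""
    from sgaburden.validation import run_prognosis_study

    r = run_prognosis_study(seed=11)
    assert r["auc_clinical_genetic"] > r["auc_clinical"]
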