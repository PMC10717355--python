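"""Collapsing scan: Fisher tests, risk score, permutation null, FDR, tiers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sgaburden.burden import (
    BurdenConfig,
    bh_fdr,
    fisher_collapsing_test,
    gene_burden_scan,
    neutral_background_filter,
    permutation_null,
    risk_score,
    run_burden_analysis,
    select_genes,
)
from sgaburden.variants import GeneTypeCountMatrix, VariantType


def hypergeom_tail_oracle(k_case, n_case, k_ctrl, n_ctrl):
    """Exact P(X >= k_case) by direct enumeration of hypergeometric terms."""
    total = k_case + k_ctrl
    n = n_case + n_ctrl
    num = 0
    for j in range(k_case, min(total, n_case) + 1):
        num += math.comb(n_case, j) * math.comb(n_ctrl, total - j)
    return num / math.comb(n, total)


class TestFisherCollapsing:
    def test_empty_table(self):
        assert fisher_collapsing_test(0, 10, 0, 10) == 1.0

    def test_known_tail_probability(self):
        # P(X >= 5) with N=20, K=5, n=10 = C(10,5)C(10,0)/C(20,5)
        p = fisher_collapsing_test(5, 10, 0, 10)
        assert p == pytest.approx(252 / 15504, rel=1e-12)

    def test_two_by_two_tail(self):
        # 1 - C(2,0)C(2,2)/C(4,2) = 5/6
        assert fisher_collapsing_test(1, 2, 1, 2) == pytest.approx(5 / 6, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(1, 15, 2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            assert fisher_collapsing_test(k1, n1, k2, n2) == pytest.approx(
                hypergeom_tail_oracle(k1, n1, k2, n2), rel=1e-10
            )

    def test_monotone_in_case_carriers(self):
        """With all margins fixed, shifting carriers into cases shrinks p."""
        total, n1, n2 = 8, 10, 12
        ps = [
            fisher_collapsing_test(k, n1, total - k, n2)
            for k in range(0, min(total, n1) + 1)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(11, 10, 0, 10), (0, 10, -1, 10), (0, 0, 0, 5)])
    def test_invalid_counts(self, args):
        with pytest.raises(ValueError):
            fisher_collapsing_test(*args)


class TestRiskScore:
    @pytest.mark.parametrize(
        "p_ptv,p_mis,expected",
        [(1.0, 1.0, 0.0), (0.01, 1.0, 4.0), (0.001, 0.01, 8.0), (0.1, 0.1, 3.0)],
    )
    def test_formula(self, p_ptv, p_mis, expected):
        assert risk_score(p_ptv, p_mis) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.5, 0.0), (1.1, 0.5), (-0.1, 0.5)])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            risk_score(*bad)

    def test_strictly_decreasing_in_each_argument(self):
        grid = [1.0, 0.5, 0.1, 0.01, 1e-6]
        for p_mis in (1.0, 0.3):
            scores = [risk_score(p, p_mis) for p in grid]
            assert all(a < b for a, b in zip(scores, scores[1:]))
        for p_ptv in (1.0, 0.3):
            scores = [risk_score(p_ptv, p) for p in grid]
            assert all(a < b for a, b in zip(scores, scores[1:]))


class TestBhFdr:
    def _oracle(self, p):
        """Independent BH step-up: q_(i) = min over j>=i of p_(j) * m / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q[idx] = running
        return q

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ],
    )
    def test_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_step_up_oracle_and_dominates_p(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_fdr(p)
            np.testing.assert_allclose(q, self._oracle(p), atol=1e-12)
            assert (q >= p - 1e-12).all()

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestGeneBurdenScan:
    def test_balanced_gene_has_p_one(self):
        counts = {vt: np.zeros((1, 8), dtype=np.int32) for vt in VariantType}
        counts[VariantType.PTV][0] = [1, 1, 0, 0, 1, 1, 0, 0]
        mat = GeneTypeCountMatrix(["G"], [f"S{i}" for i in range(8)], counts)
        is_case = np.array([1, 0, 1, 0] * 2, dtype=bool)
        res = gene_burden_scan(mat, is_case)
        # equal carriers, equal group sizes: no evidence of enrichment
        assert res.loc[0, "p_PTV"] > 0.5
        assert res.loc[0, "p_SYN"] == 1.0

    def test_scan_equals_per_gene_fisher(self, small_matrix, small_cohort):
        is_case = (small_cohort.samples["group"] == "SGA").to_numpy()
        res = gene_burden_scan(small_matrix, is_case)
        n_case = int(is_case.sum())
        n_ctrl = int((~is_case).sum())
        for vt in VariantType:
            carriers = small_matrix.carriers(vt)
            for gi in range(0, small_matrix.n_genes, 7):
                k_case = int(carriers[gi, is_case].sum())
                k_ctrl = int(carriers[gi, ~is_case].sum())
                expected = fisher_collapsing_test(k_case, n_case, k_ctrl, n_ctrl)
                assert res.loc[gi, f"p_{vt.value}"] == pytest.approx(expected, rel=1e-10)

    def test_single_group_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            gene_burden_scan(small_matrix, np.ones(small_matrix.n_samples, dtype=bool))


class TestPermutationNull:
    def _exact_null(self, mat, n_case):
        """Exact risk-score null by enumerating every label assignment."""
        n = mat.n_samples
        scores = []
        for case_idx in itertools.combinations(range(n), n_case):
            is_case = np.zeros(n, dtype=bool)
            is_case[list(case_idx)] = True
            res = gene_burden_scan(mat, is_case)
            scores.append(res["risk_score"].to_numpy())
        return np.array(scores)  # (n_assignments, n_genes)

    def test_matches_exact_enumeration(self, tiny_matrix):
        """perm_p approximates the exact exchangeable tail over all C(6,3)
        label assignments."""
        is_case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        observed = gene_burden_scan(tiny_matrix, is_case)["risk_score"].to_numpy()
        null = self._exact_null(tiny_matrix, 3)
        exact_tail = (null >= observed[None, :] - 1e-12).mean(axis=0)
        B = 4000
        perm_p = permutation_null(tiny_matrix, is_case, n_permutations=B, seed=0)
        # add-one estimator converges to the exact tail
        se = np.sqrt(exact_tail * (1 - exact_tail) / B)
        assert (np.abs(perm_p - exact_tail) < 4 * se + 2 / B).all()

    def test_bounds_and_reproducibility(self, small_matrix, small_cohort):
        is_case = (small_cohort.samples["group"] == "SGA").to_numpy()
        p1 = permutation_null(small_matrix, is_case, n_permutations=100, seed=5)
        p2 = permutation_null(small_matrix, is_case, n_permutations=100, seed=5)
        np.testing.assert_array_equal(p1, p2)
        assert (p1 >= 1 / 101).all() and (p1 <= 1.0).all()

    def test_gene_order_irrelevant(self, tiny_matrix):
        is_case = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        p = permutation_null(tiny_matrix, is_case, n_permutations=500, seed=3)
        perm = [2, 0, 1]
        shuffled = GeneTypeCountMatrix(
            [tiny_matrix.genes[i] for i in perm],
            tiny_matrix.samples,
            {vt: m[perm] for vt, m in tiny_matrix.counts.items()},
        )
        p_shuf = permutation_null(shuffled, is_case, n_permutations=500, seed=3)
        np.testing.assert_allclose(p_shuf, p[perm])

    def test_requires_permutations(self, tiny_matrix):
        with pytest.raises(ValueError):
            permutation_null(tiny_matrix, np.array([1, 1, 1, 0, 0, 0], dtype=bool), 0)


class TestSelection:
    def _frame(self, **kw):
        base = dict(
            gene=["G"],
            p_PTV=[1.0],
            p_MIS=[1.0],
            p_SYN=[1.0],
            p_NON=[1.0],
            perm_p=[1.0],
            fdr_q=[1.0],
            background_flagged=[False],
        )
        base.update({k: [v] for k, v in kw.items()})
        return pd.DataFrame(base)

    def test_background_filter_flags(self):
        res = neutral_background_filter(self._frame(p_SYN=0.01))
        assert res.loc[0, "background_flagged"]
        res = neutral_background_filter(self._frame())
        assert not res.loc[0, "background_flagged"]

    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(p_PTV=0.04, p_MIS=0.5, fdr_q=0.5), "risk_gene"),
            (dict(p_PTV=0.005, fdr_q=0.005), "potential_causative"),
            (dict(p_PTV=0.005, fdr_q=0.005, background_flagged=True), "none"),
            (dict(p_MIS=0.04), "risk_gene"),
            (dict(p_PTV=0.005, fdr_q=0.5), "risk_gene"),  # FDR gate fails
            (dict(), "none"),
        ],
    )
    def test_tiers(self, kw, expected):
        res = select_genes(self._frame(**kw))
        assert res.loc[0, "tier"] == expected

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="perm_p"):
            select_genes(self._frame().drop(columns="perm_p"))


def test_full_analysis_recovers_planted_gene(small_matrix, small_cohort):
    """The planted PTV gene tops the risk-score ranking; the SYN-confounded
    gene is background-flagged; zero-carrier genes are never selected."""
    is_case = (small_cohort.samples["group"] == "SGA").to_numpy()
    res = run_burden_analysis(
        small_matrix, is_case, BurdenConfig(n_permutations=300, seed=2)
    )
    best = res.sort_values("risk_score", ascending=False).iloc[0]
    assert best["gene"] == "G0000"
    assert res.set_index("gene").loc["G0030", "background_flagged"]
    empty = res[
        (res[[f"case_carriers_{vt.value}" for vt in VariantType]].sum(axis=1) == 0)
        & (res[[f"control_carriers_{vt.value}" for vt in VariantType]].sum(axis=1) == 0)
    ]
    assert (empty["tier"] == "none").all()
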