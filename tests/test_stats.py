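"""Moderated t, rank product, combination and Storey correction."""

import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from sialoquant.stats import (
    TestResult as SiteCall,
    combine_tests,
    moderated_t,
    rank_product,
    replicate_log_ratios,
    significance_filter,
    storey_qvalues,
)

from conftest import make_matrix


def null_matrix(two_group_matrix, m=200, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    return two_group_matrix(rng.normal(0.0, sd, (m, 12)))


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_t(self, two_group_matrix):
        rng = np.random.default_rng(11)
        values = rng.normal(0, 1, (40, 12))
        matrix = two_group_matrix(values)
        fit = moderated_t(matrix, "ST3GAL4", "mock", prior_df=0.0)
        case_cols = matrix.samples_for(condition="ST3GAL4")
        ctrl_cols = matrix.samples_for(condition="mock")
        t_ref, p_ref = sps.ttest_ind(
            matrix.data[case_cols], matrix.data[ctrl_cols], axis=1, equal_var=True
        )
        assert np.allclose(fit.t, t_ref, atol=1e-10)
        assert np.allclose(fit.p, p_ref, atol=1e-10)

    def test_infinite_prior_orders_by_mean_difference(self, two_group_matrix):
        rng = np.random.default_rng(12)
        matrix = two_group_matrix(rng.normal(0, 1, (60, 12)))
        fit = moderated_t(matrix, "ST3GAL4", "mock", prior_df=math.inf)
        assert np.allclose(fit.posterior_s2, fit.prior_s2)
        order_t = np.argsort(-np.abs(fit.t))
        order_d = np.argsort(-np.abs(fit.mean_diff))
        assert list(order_t) == list(order_d)

    def test_null_calibration(self, two_group_matrix):
        # 2000 null features, 6 vs 6 split over three runs: p below 0.05
        # should occur for about 5% of features
        matrix = null_matrix(two_group_matrix, m=2000, seed=123)
        fit = moderated_t(matrix, "ST3GAL4", "mock")
        frac = float(np.mean(fit.p < 0.05))
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_untested_features_reported(self, two_group_matrix):
        values = np.random.default_rng(0).normal(0, 1, (3, 12))
        values[1, [0, 1, 4, 5, 8]] = np.nan  # only one mock value left
        matrix = two_group_matrix(values)
        fit = moderated_t(matrix, "ST3GAL4", "mock")
        assert matrix.data.index[1] in fit.untested
        assert len(fit.features) == 2

    def test_agrees_with_limma(self, two_group_matrix, tmp_path):
        """Independent cross-check of the variance prior and p-values."""
        rng = np.random.default_rng(77)
        # heterogeneous variances so the prior df estimate is finite
        sd = rng.uniform(0.5, 2.0, (80, 1))
        values = rng.normal(0, 1, (80, 12)) * sd
        values[:8, 6:] += 1.0
        matrix = two_group_matrix(values)
        fit = moderated_t(matrix, "ST3GAL4", "mock")

        data = tmp_path / "m.tsv"
        matrix.data.to_csv(data, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
            cond <- rep(rep(c(0,0,1,1),3))
            fit <- eBayes(lmFit(x, model.matrix(~cond)))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s02=fit$s2.prior)
            write.table(format(out, digits=12), sep="\t", quote=FALSE)
            """
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data)],
            capture_output=True,
            text=True,
            check=True,
        )
        ref = pd.read_csv(pd.io.common.StringIO(res.stdout), sep="\t").astype(float)
        assert math.isfinite(fit.prior_df)
        assert fit.prior_df == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert fit.prior_s2 == pytest.approx(float(ref["s02"].iloc[0]), rel=1e-4)
        assert np.allclose(fit.t, ref["t"], rtol=1e-6)
        assert np.allclose(fit.p, ref["p"], rtol=1e-6)


def brute_force_rank_product(ratios: np.ndarray):
    """Enumerate all per-replicate rank permutations (tiny instances only)."""
    m, k = ratios.shape
    rank_up = np.column_stack(
        [sps.rankdata(-ratios[:, j]) for j in range(k)]
    )
    rp_obs_up = np.exp(np.mean(np.log(rank_up), axis=1))
    rp_obs_down = np.exp(np.mean(np.log((m + 1) - rank_up), axis=1))
    base = np.arange(1, m + 1, dtype=float)
    count_up = np.zeros(m)
    count_down = np.zeros(m)
    total = 0
    for cols in itertools.product(itertools.permutations(base), repeat=k):
        perm = np.column_stack(cols)
        count_up += np.exp(np.mean(np.log(perm), axis=1)) <= rp_obs_up
        count_down += np.exp(np.mean(np.log((m + 1) - perm), axis=1)) <= rp_obs_down
        total += 1
    return (count_up + 1) / (total + 1), (count_down + 1) / (total + 1)


class TestRankProduct:
    def test_extreme_feature_has_minimum_rp(self):
        ratios = pd.DataFrame([[3.0, 2.0], [1.0, 1.0], [-2.0, -3.0]])
        res = rank_product(ratios, exhaustive=True)
        assert res.rank_product_up[0] == pytest.approx(1.0)
        assert res.rank_product_down[2] == pytest.approx(1.0)

    def test_exhaustive_equals_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            ratios = rng.normal(0, 1, (4, 2))
            res = rank_product(pd.DataFrame(ratios), exhaustive=True)
            p_up, p_down = brute_force_rank_product(ratios)
            assert res.n_perm == (math.factorial(4)) ** 2
            assert np.allclose(res.p_up, p_up)
            assert np.allclose(res.p_down, p_down)

    def test_seed_determinism_and_stability(self):
        rng = np.random.default_rng(9)
        ratios = pd.DataFrame(rng.normal(0, 1, (30, 3)))
        a = rank_product(ratios, n_perm=2000, seed=4)
        b = rank_product(ratios, n_perm=2000, seed=4)
        c = rank_product(ratios, n_perm=2000, seed=5)
        assert np.array_equal(a.p_up, b.p_up)
        assert np.allclose(a.p_up, c.p_up, atol=2.0 / math.sqrt(2000))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rank_product(pd.DataFrame([[1.0], [2.0]]))  # one replicate
        with pytest.raises(ValueError):
            rank_product(pd.DataFrame([[1.0, np.nan], [2.0, 1.0]]))


class TestCombine:
    def test_max_rule(self):
        out = combine_tests([0.01, 0.5], [0.04, 0.001])
        assert list(out) == [0.04, 0.5]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            combine_tests([0.1], [0.1, 0.2])

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.integers(0, 10_000),
    )
    def test_never_below_inputs(self, p1, seed):
        rng = np.random.default_rng(seed)
        p2 = rng.uniform(0, 1, len(p1))
        out = combine_tests(p1, p2)
        assert np.all(out >= np.asarray(p1))
        assert np.all(out >= p2)


class TestStorey:
    def test_closed_form_with_ties(self):
        # all m p-values tied: min over p_j >= p_i of pi0*m*p_j/rank(p_j)
        # is attained at the deepest rank m, so q = pi0 * p
        p = np.full(100, 1e-6)
        q, est = storey_qvalues(p, pi0=1.0)
        assert np.allclose(q, 1e-6)
        assert est.pi0 == 1.0
        # and a unique smallest p at rank 1 gets q = pi0 * m * p / 1 when
        # the rest of the p-values are large
        p2 = np.concatenate([[1e-6], np.linspace(0.5, 1.0, 99)])
        q2, _ = storey_qvalues(p2, pi0=1.0)
        assert q2[0] == pytest.approx(1e-4)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(2024)
        p = rng.uniform(0, 1, 5000)
        _, est = storey_qvalues(p)
        assert 0.9 <= est.pi0 <= 1.0

    @given(st.integers(0, 100_000))
    def test_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate(
            [rng.uniform(0, 1, 150), rng.beta(0.2, 5.0, 50)]
        )
        q, est = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= est.pi0 * p - 1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([])


def _result(q=0.03, fold=2.9, feature="f1"):
    return SiteCall(
        feature=feature,
        fold_change=fold,
        log2_fold_change=math.log2(fold),
        p_moderated=0.01,
        p_rankproduct=0.01,
        p_combined=0.02,
        q=q,
        direction="up" if fold > 1 else "down",
    )


class TestSignificanceFilter:
    SEQUONS = {"f1": "valid", "f2": "potential_NG", "f3": "invalid"}
    MEMBRANE = {"P1": True, "P2": False}
    ACC = {"f1": "P1", "f2": "P1", "f3": "P1"}

    def run(self, results):
        return significance_filter(
            results, self.SEQUONS, self.MEMBRANE, self.ACC, alpha=0.05
        )

    def test_all_gates_pass(self):
        inc, dec, counts = self.run([_result()])
        assert [r.feature for r in inc] == ["f1"] and not dec
        assert counts["kept"] == 1

    def test_fdr_gate(self):
        inc, dec, counts = self.run([_result(q=0.06)])
        assert not inc and counts["fdr"] == 1

    def test_membrane_gate(self):
        res = _result()
        inc, _, counts = significance_filter(
            [res], self.SEQUONS, self.MEMBRANE, {"f1": "P2"}
        )
        assert not inc and counts["membrane"] == 1

    def test_unknown_membrane_excluded(self):
        inc, _, counts = significance_filter(
            [_result()], self.SEQUONS, self.MEMBRANE, {"f1": "P9"}
        )
        assert not inc and counts["membrane_unknown"] == 1

    def test_sequon_gate_and_ng_caveat(self):
        bad = _result(feature="f3")
        ng = _result(feature="f2")
        down = _result(feature="f1", fold=0.5)
        inc, dec, counts = self.run([bad, ng, down])
        assert counts["sequon"] == 1
        assert [r.feature for r in inc] == ["f2"]
        assert inc[0].caveat == "potential_NG"
        assert [r.feature for r in dec] == ["f1"]
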