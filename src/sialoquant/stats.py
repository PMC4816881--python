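"""Differential testing: moderated t, rank product, combination, Storey FDR.

Two complementary tests are run per glycosite feature and a site must be
supported by both:

* an empirical-Bayes **moderated t** in the style of limma: per-feature
  pooled variances are shrunk toward a global prior estimated by matching
  moments of log s^2 (digamma/trigamma inversion), buying degrees of freedom
  at three replicates;
* a nonparametric **rank product** over the per-replicate condition log
  ratios, calibrated by permutation (feature labels shuffled independently
  within each replicate, identical draws for the up and down statistics).

The per-side combination is the intersection (max-p) rule; the reported
two-sided combined p is twice the better side, capped at 1.  Multiple testing
is corrected with Storey q-values, estimating the null fraction pi0 on a
lambda grid.  The final biological filter keeps q <= alpha features whose
deamidated site lies in an N-glycosylation sequon (NG sites flagged as
potential) on a membrane-associated protein.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .quant import IntensityMatrix

__all__ = [
    "ModeratedTestFit",
    "RankProductResult",
    "Pi0Estimate",
    "TestResult",
    "moderated_t",
    "replicate_log_ratios",
    "rank_product",
    "combine_tests",
    "storey_qvalues",
    "differential_test",
    "significance_filter",
]


# ---------------------------------------------------------------------------
# Moderated t


@dataclass
class ModeratedTestFit:
    """Per-feature moderated-t results plus the global variance prior."""

    features: list
    mean_diff: np.ndarray  # case minus control, log2
    s2: np.ndarray  # pooled within-condition variance
    df_residual: np.ndarray
    prior_df: float
    prior_s2: float
    posterior_s2: np.ndarray
    t: np.ndarray
    p: np.ndarray  # two-sided
    untested: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_diff": self.mean_diff,
                "s2": self.s2,
                "df": self.df_residual,
                "posterior_s2": self.posterior_s2,
                "t": self.t,
                "p": self.p,
            },
            index=self.features,
        )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0^2).

    Works on z = log s^2: E z = log s0^2 + digamma(d/2) - log(d/2)
    + [log(d0/2) - digamma(d0/2)], Var z = trigamma(d/2) + trigamma(d0/2).
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    # unbiased-ish correction as in the standard implementation
    e_var = float(np.mean((e - e_mean) ** 2) * len(e) / (len(e) - 1))
    e_var -= float(np.mean(special.polygamma(1, d / 2.0)))
    if e_var <= 0:
        # no detectable variance heterogeneity: degenerate prior, all
        # variances shrink fully to the average sample variance
        return math.inf, float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_2


def moderated_t(
    matrix: IntensityMatrix,
    case: str,
    control: str,
    prior_df: float | None = None,
    min_per_condition: int = 2,
) -> ModeratedTestFit:
    """Empirical-Bayes moderated two-sample t test per feature.

    ``case``/``control`` name the two condition labels in the design; the
    reported mean difference is case minus control (log2).  Features with
    fewer than ``min_per_condition`` non-missing values in either condition
    are reported as untested.  ``prior_df`` overrides the estimated prior
    degrees of freedom (0 recovers the ordinary pooled t; large values
    approach ordering by mean difference).
    """
    case_cols = matrix.samples_for(condition=case)
    ctrl_cols = matrix.samples_for(condition=control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each condition needs at least 2 samples overall")

    a = matrix.data[case_cols].to_numpy(dtype=float)
    b = matrix.data[ctrl_cols].to_numpy(dtype=float)
    n1_all = (~np.isnan(a)).sum(axis=1).astype(float)
    n2_all = (~np.isnan(b)).sum(axis=1).astype(float)
    testable = (n1_all >= min_per_condition) & (n2_all >= min_per_condition)
    features = [f for f, ok in zip(matrix.data.index, testable) if ok]
    untested = [f for f, ok in zip(matrix.data.index, testable) if not ok]
    a, b = a[testable], b[testable]
    n1, n2 = n1_all[testable], n2_all[testable]
    with np.errstate(invalid="ignore"):
        mean_diff = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    df = n1 + n2 - 2.0
    s2 = ((n1 - 1.0) * var_a + (n2 - 1.0) * var_b) / df

    if prior_df is None:
        d0, s0_2 = _fit_f_dist(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_f_dist(s2, df)
    if math.isinf(d0):
        post_s2 = np.full_like(s2, s0_2)
        total_df = np.full_like(df, np.inf)
    elif d0 == 0:
        post_s2 = s2.copy()
        total_df = df.copy()
    else:
        post_s2 = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / np.sqrt(post_s2 * (1.0 / n1 + 1.0 / n2))
    finite_df = np.where(np.isfinite(total_df), total_df, 1e12)
    p = 2.0 * sps.t.sf(np.abs(t), finite_df)
    return ModeratedTestFit(
        features=features,
        mean_diff=mean_diff,
        s2=s2,
        df_residual=df,
        prior_df=d0,
        prior_s2=s0_2,
        posterior_s2=post_s2,
        t=t,
        p=np.clip(p, 0.0, 1.0),
        untested=untested,
    )


# ---------------------------------------------------------------------------
# Rank product


@dataclass
class RankProductResult:
    features: list
    rank_product_up: np.ndarray
    rank_product_down: np.ndarray
    p_up: np.ndarray
    p_down: np.ndarray
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rp_up": self.rank_product_up,
                "rp_down": self.rank_product_down,
                "p_up": self.p_up,
                "p_down": self.p_down,
            },
            index=self.features,
        )


def replicate_log_ratios(
    matrix: IntensityMatrix, case: str, control: str
) -> pd.DataFrame:
    """Per-replicate (per-run) case-minus-control mean log2 ratios.

    One column per run; the ratio is the difference of the condition means of
    that run's channels, NaN when either condition is entirely missing.
    """
    out = {}
    for run in matrix.runs:
        c_cols = matrix.samples_for(run=run, condition=case)
        m_cols = matrix.samples_for(run=run, condition=control)
        if not c_cols or not m_cols:
            raise ValueError(f"run {run!r} lacks one of the conditions")
        out[run] = matrix.data[c_cols].mean(axis=1, skipna=True) - matrix.data[
            m_cols
        ].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=matrix.data.index)


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(ranks), axis=1))


def rank_product(
    ratios: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> RankProductResult:
    """Rank-product test on a features x replicates log-ratio table.

    Within each replicate, features are ranked by ratio (rank 1 = most
    up-regulated for the up statistic; the down statistic uses the reversed
    ranks from the same ordering).  RP is the geometric mean of the ranks.
    The permutation null shuffles feature labels independently within each
    replicate; up and down p-values share the same draws and use add-one
    smoothing, p = (1 + #{RP_perm <= RP_obs}) / (n_perm + 1).

    ``exhaustive=True`` enumerates all (m!)^k arrangements instead of
    sampling (only sensible for tiny m and k).
    """
    data = ratios.to_numpy(dtype=float)
    m, k = data.shape
    if k < 2:
        raise ValueError("rank product needs at least 2 replicates")
    if np.isnan(data).any():
        raise ValueError("rank product input must be complete (drop NaN features first)")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    # descending ranks: rank 1 for the largest ratio; ties share average rank
    rank_up = np.column_stack(
        [sps.rankdata(-data[:, j], method="average") for j in range(k)]
    )
    rank_down = (m + 1) - rank_up
    rp_up = _geometric_mean_ranks(rank_up)
    rp_down = _geometric_mean_ranks(rank_down)

    if exhaustive:
        base = np.arange(1, m + 1, dtype=float)
        count_up = np.zeros(m)
        count_down = np.zeros(m)
        total = 0
        for cols in itertools.product(itertools.permutations(base), repeat=k):
            perm = np.column_stack(cols)
            rp_perm_up = _geometric_mean_ranks(perm)
            rp_perm_down = _geometric_mean_ranks((m + 1) - perm)
            count_up += rp_perm_up <= rp_up
            count_down += rp_perm_down <= rp_down
            total += 1
        p_up = (count_up + 1.0) / (total + 1.0)
        p_down = (count_down + 1.0) / (total + 1.0)
        return RankProductResult(
            list(ratios.index), rp_up, rp_down, p_up, p_down, total, seed, True
        )

    rng = np.random.default_rng(seed)
    count_up = np.zeros(m)
    count_down = np.zeros(m)
    # vectorized in blocks: each block draws `block` independent column permutations
    block = max(1, min(n_perm, int(2e6) // max(1, m)))
    done = 0
    log_rank = np.log(np.arange(1, m + 1, dtype=float))
    while done < n_perm:
        b = min(block, n_perm - done)
        # permuted log-ranks per column: shuffle rows of log_rank independently
        log_rp_up = np.zeros((b, m))
        log_rp_down = np.zeros((b, m))
        for _ in range(k):
            order = np.argsort(rng.random((b, m)), axis=1)
            ranks = np.empty((b, m))
            rows = np.arange(b)[:, None]
            ranks[rows, order] = np.arange(1, m + 1, dtype=float)
            log_rp_up += np.log(ranks)
            log_rp_down += np.log((m + 1) - ranks)
        rp_perm_up = np.exp(log_rp_up / k)
        rp_perm_down = np.exp(log_rp_down / k)
        count_up += (rp_perm_up <= rp_up[None, :]).sum(axis=0)
        count_down += (rp_perm_down <= rp_down[None, :]).sum(axis=0)
        done += b
    p_up = (count_up + 1.0) / (n_perm + 1.0)
    p_down = (count_down + 1.0) / (n_perm + 1.0)
    return RankProductResult(
        list(ratios.index), rp_up, rp_down, p_up, p_down, n_perm, seed, False
    )


# ---------------------------------------------------------------------------
# Combination and Storey correction


def combine_tests(
    p_mod: Sequence[float] | np.ndarray,
    p_rp: Sequence[float] | np.ndarray,
    rule: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Combine two p-value vectors feature-wise (default: intersection/max rule).

    The max rule demands support from both tests and never yields a combined
    p below either input.  ``rule`` may swap in another combiner with the
    same signature.
    """
    a = np.asarray(p_mod, dtype=float)
    b = np.asarray(p_rp, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if rule is None:
        return np.maximum(a, b)
    return np.asarray(rule(a, b), dtype=float)


@dataclass
class Pi0Estimate:
    lambda_grid: np.ndarray
    raw: np.ndarray
    pi0: float


DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.95, 0.05)


def storey_qvalues(
    p: Sequence[float] | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, Pi0Estimate]:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid,
    smoothed with a cubic polynomial fit and evaluated at the grid maximum,
    then clipped to (0, 1].  For fewer than 100 p-values the noisy smoothing
    is skipped in favor of the fixed lambda = 0.5 estimate.  ``pi0`` forces
    the null fraction instead of estimating it.  q_i is the running minimum
    of pi0 * m * p_(j) / j over p_(j) >= p_i.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if pi0 is None:
        if m < 100 or len(grid) < 4:
            lam = 0.5
            pi0 = (p > lam).sum() / (m * (1.0 - lam))
        else:
            coeffs = np.polyfit(grid, raw, 3)
            pi0 = float(np.polyval(coeffs, grid.max()))
        pi0 = float(min(max(pi0, 1.0 / m), 1.0))  # clip to (0, 1]
    elif not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q, Pi0Estimate(grid, raw, pi0)


# ---------------------------------------------------------------------------
# End-to-end test driver and biological filter


@dataclass
class TestResult:
    """Final per-feature differential-sialylation call."""

    feature: Hashable
    fold_change: float  # linear scale, case / control
    log2_fold_change: float
    p_moderated: float
    p_rankproduct: float
    p_combined: float
    q: float = math.nan
    direction: str = ""  # "up" or "down"
    significant: bool = False
    caveat: str = ""


def differential_test(
    matrix: IntensityMatrix,
    case: str,
    control: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    prior_df: float | None = None,
    combination: str = "union",
) -> tuple[list[TestResult], ModeratedTestFit, RankProductResult, Pi0Estimate]:
    """Run the combined moderated-t / rank-product procedure with Storey FDR.

    Two combination strategies are available:

    * ``"union"`` (default): a feature counts as supported when *either* test
      finds it, Bonferroni-corrected — p = min(1, 2 min(p_mod, p_rp)) with
      both inputs two-sided.  This is valid under arbitrary dependence and
      keeps the moderated test's power; the rank product contributes
      robustness for features whose variance is misbehaved.
    * ``"intersection"``: a feature must be supported by both tests —
      per side, p = max(one-sided p_mod, one-sided p_rp), doubled for
      two-sidedness.  Very conservative: a feature's rank-product permutation
      p cannot beat ~(rank/m)^k, so with many concurrent effects only the
      very strongest survive an FDR cut regardless of sample size.
    """
    if combination not in ("union", "intersection"):
        raise ValueError(f"unknown combination strategy {combination!r}")
    fit = moderated_t(matrix, case, control, prior_df=prior_df)
    ratios = replicate_log_ratios(matrix, case, control).loc[fit.features]
    complete = ratios.dropna(axis=0, how="any")
    rp = rank_product(complete, n_perm=n_perm, seed=seed)

    rp_up = pd.Series(rp.p_up, index=rp.features)
    rp_down = pd.Series(rp.p_down, index=rp.features)
    results: list[TestResult] = []
    p_combined_all = []
    for i, feat in enumerate(fit.features):
        if feat not in rp_up.index:
            continue
        diff = fit.mean_diff[i]
        p_two = fit.p[i]
        p_mod_up = p_two / 2.0 if diff > 0 else 1.0 - p_two / 2.0
        p_mod_down = 1.0 - p_mod_up
        if combination == "intersection":
            comb_up = max(p_mod_up, rp_up[feat])
            comb_down = max(p_mod_down, rp_down[feat])
            p_comb = min(1.0, 2.0 * min(comb_up, comb_down))
        else:
            p_rp_two = min(1.0, 2.0 * min(rp_up[feat], rp_down[feat]))
            p_comb = min(1.0, 2.0 * min(p_two, p_rp_two))
        # the reported direction follows the sign of the mean log ratio
        direction = "up" if diff > 0 else "down"
        p_rp_side = rp_up[feat] if direction == "up" else rp_down[feat]
        results.append(
            TestResult(
                feature=feat,
                fold_change=float(2.0**diff),
                log2_fold_change=float(diff),
                p_moderated=float(p_two),
                p_rankproduct=float(p_rp_side),
                p_combined=float(p_comb),
                direction=direction,
            )
        )
        p_combined_all.append(p_comb)

    q, pi0 = storey_qvalues(np.asarray(p_combined_all))
    for res, qi in zip(results, q):
        res.q = float(qi)
        res.significant = bool(qi <= alpha)
    return results, fit, rp, pi0


def significance_filter(
    results: Iterable[TestResult],
    sequons: Mapping[Hashable, str],
    membrane: Mapping[str, bool],
    accession_of: Mapping[Hashable, str] | Callable[[Hashable], str],
    alpha: float = 0.05,
) -> tuple[list[TestResult], list[TestResult], dict[str, int]]:
    """Apply the biological gates and split calls by direction.

    Keeps features with q <= alpha whose sequon status is ``valid`` or
    ``potential_NG`` and whose protein is membrane-associated; NG sites carry
    a ``potential_NG`` caveat.  Features whose accession is absent from the
    membrane annotation are excluded and counted.  Returns (increased,
    decreased, rejection counts).
    """
    get_acc = accession_of if callable(accession_of) else accession_of.__getitem__
    increased, decreased = [], []
    counts = {
        "fdr": 0,
        "sequon": 0,
        "membrane": 0,
        "membrane_unknown": 0,
        "kept": 0,
    }
    for res in results:
        if not (res.q <= alpha):
            counts["fdr"] += 1
            continue
        status = sequons.get(res.feature, "invalid")
        if status not in ("valid", "potential_NG"):
            counts["sequon"] += 1
            continue
        acc = get_acc(res.feature)
        if acc not in membrane:
            counts["membrane_unknown"] += 1
            continue
        if not membrane[acc]:
            counts["membrane"] += 1
            continue
        if status == "potential_NG":
            res.caveat = "potential_NG"
        counts["kept"] += 1
        (increased if res.fold_change > 1.0 else decreased).append(res)
    return increased, decreased, counts
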