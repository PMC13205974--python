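"""Nonparametric group comparison framework for phenotype kinematics.

Phenotype groups are unbalanced and several metrics deviate from normality
(recorded via a per-group Shapiro-Wilk gate), so comparisons are rank-based:
a Kruskal-Wallis omnibus across phenotypes, Brunner-Munzel post hoc pairwise
tests (robust to heteroscedasticity and unequal n), Benjamini-Hochberg FDR
adjustment within each variable's three-pair family, and rank-biserial
correlation as the effect size.  A complementary sensitivity battery re-runs
each two-sample comparison under eight tests to check that conclusions do not
hinge on the choice of test.

Sign convention: ``rank_biserial(x, y) = 2 * P(x < y) - 1`` with ties counted
one half, so a *first* group that is stochastically larger yields a negative
value; complete separation gives -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError

_ENUMERATION_LIMIT = 200_000
_MC_RESAMPLES = 10_000

SIGNIFICANCE_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p_adjusted: float) -> str:
    if not np.isfinite(p_adjusted):
        return "na"
    for threshold, tier in SIGNIFICANCE_TIERS:
        if p_adjusted < threshold:
            return tier
    return "ns"


def relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank estimate of P(x < y) + 0.5 * P(x = y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    less = np.sum(x[:, None] < y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float((less + 0.5 * ties) / (len(x) * len(y)))


@dataclass
class BrunnerMunzelResult:
    statistic: float
    pvalue: float
    relative_effect: float
    method: str  # "t-approximation" | "exact-permutation" | "mc-permutation"


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, seed: int | None) -> tuple[float, str]:
    """Two-sided permutation p for the relative effect, exact when feasible."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    observed = abs(relative_effect(x, y) - 0.5)
    if comb(n + m, n) <= _ENUMERATION_LIMIT:
        idx_all = np.arange(n + m)
        count = 0
        total = 0
        for xs in combinations(idx_all, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(xs)] = True
            stat = abs(relative_effect(pooled[mask], pooled[~mask]) - 0.5)
            count += stat >= observed - 1e-12
            total += 1
        return count / total, "exact-permutation"
    rng = np.random.default_rng(seed)
    count = 1  # include the observed arrangement
    for _ in range(_MC_RESAMPLES):
        perm = rng.permutation(pooled)
        stat = abs(relative_effect(perm[:n], perm[n:]) - 0.5)
        count += stat >= observed - 1e-12
    return count / (_MC_RESAMPLES + 1), "mc-permutation"


def brunner_munzel(x, y, seed: int | None = None) -> BrunnerMunzelResult:
    """Two-sided Brunner-Munzel test with a permutation fallback.

    The standard Satterthwaite-type t approximation is undefined when either
    within-group rank variance is zero (constant samples or complete
    separation); in that case a permutation p value on the relative effect is
    reported instead (full enumeration when the number of arrangements is
    modest, otherwise seeded Monte-Carlo).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidArgumentError("both samples need at least 2 values")
    p_hat = relative_effect(x, y)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.brunnermunzel(x, y, alternative="two-sided", distribution="t")
    if np.isfinite(res.statistic) and np.isfinite(res.pvalue):
        return BrunnerMunzelResult(float(res.statistic), float(res.pvalue), p_hat,
                                   "t-approximation")
    p, method = _permutation_pvalue(x, y, seed)
    statistic = np.inf if p_hat > 0.5 else (-np.inf if p_hat < 0.5 else 0.0)
    return BrunnerMunzelResult(float(statistic), float(p), p_hat, method)


def rank_biserial(x, y) -> float:
    """Effect size 2 * P(x < y) - 1, ties counted one half."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidArgumentError("samples must be non-empty")
    return 2.0 * relative_effect(x, y) - 1.0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(n)
    out[order] = adjusted_sorted
    return out


@dataclass
class GroupSummary:
    label: int
    n: int
    mean: float
    sd: float
    median: float
    iqr: float
    shapiro_p: float | None = None


@dataclass
class ComparisonResult:
    """One pairwise phenotype contrast for one variable."""

    variable: str
    pair: tuple[int, int]
    p_raw: float
    p_adjusted: float
    rbc: float
    significance: str
    method: str = "t-approximation"


@dataclass
class OmnibusResult:
    variable: str
    omnibus_p: float
    group_summaries: list[GroupSummary] = field(default_factory=list)
    comparisons: list[ComparisonResult] = field(default_factory=list)


def _summarize_group(label: int, values: np.ndarray) -> GroupSummary:
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quantiles
    shapiro_p = None
    if len(values) >= 3 and np.ptp(values) > 0:
        shapiro_p = float(stats.shapiro(values).pvalue)
    return GroupSummary(
        label=label,
        n=len(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        median=float(np.median(values)),
        iqr=float(q3 - q1),
        shapiro_p=shapiro_p,
    )


def omnibus_and_posthoc(values, labels, family: str = "variable",
                        seed: int | None = None) -> OmnibusResult:
    """Kruskal-Wallis omnibus plus BH-adjusted Brunner-Munzel pairwise tests.

    ``values`` is the per-subject metric, ``labels`` the phenotype indices.
    BH adjustment is applied within this variable's family of pairwise p
    values.  Pairs with a group of fewer than 2 members are flagged
    untestable (NaN p) but the omnibus still runs on the valid groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    groups = {g: values[labels == g] for g in uniq}
    testable = [g for g in uniq if len(groups[g]) >= 2]
    if len(testable) < 2:
        raise InvalidArgumentError("need at least 2 groups with >= 2 members")
    omnibus_p = float(stats.kruskal(*[groups[g] for g in testable]).pvalue)
    summaries = [_summarize_group(g, groups[g]) for g in uniq]

    pairs, raw, rbcs, methods = [], [], [], []
    for a, b in combinations(uniq, 2):
        pairs.append((a, b))
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            raw.append(np.nan)
            rbcs.append(np.nan)
            methods.append("untestable")
            continue
        bm = brunner_munzel(groups[a], groups[b], seed=seed)
        raw.append(bm.pvalue)
        rbcs.append(rank_biserial(groups[a], groups[b]))
        methods.append(bm.method)
    finite = np.isfinite(raw)
    adjusted = np.full(len(raw), np.nan)
    if finite.any():
        adjusted[finite] = bh_adjust(np.asarray(raw)[finite])
    comparisons = [
        ComparisonResult(
            variable=family,
            pair=pair,
            p_raw=float(p),
            p_adjusted=float(q),
            rbc=float(r),
            significance=significance_tier(q),
            method=m,
        )
        for pair, p, q, r, m in zip(pairs, raw, adjusted, rbcs, methods)
    ]
    return OmnibusResult(family, omnibus_p, summaries, comparisons)


def comparisons_table(results: list[OmnibusResult]) -> pd.DataFrame:
    """Flatten omnibus results into a publication-style long table."""
    rows = []
    for res in results:
        for cmp_ in res.comparisons:
            rows.append(
                {
                    "variable": res.variable,
                    "pair": f"T{cmp_.pair[0]} vs. T{cmp_.pair[1]}",
                    "omnibus_p": res.omnibus_p,
                    "p_raw": cmp_.p_raw,
                    "p_adjusted": cmp_.p_adjusted,
                    "rbc": cmp_.rbc,
                    "significance": cmp_.significance,
                }
            )
    return pd.DataFrame(rows)


SENSITIVITY_TESTS = (
    "brunner_munzel",
    "welch_t",
    "student_t",
    "mann_whitney",
    "kruskal_wallis",
    "kolmogorov_smirnov",
    "mood_median",
    "anderson_darling",
)


def sensitivity_battery(x, y, seed: int = 0,
                        ad_resamples: int = 1999) -> tuple[dict[str, float], str]:
    """Eight two-sample tests on the same contrast, plus a consistency verdict.

    Anderson-Darling uses the k-sample statistic with a seeded permutation p
    value.  Tests undefined on the input (e.g. constant samples) report NaN.
    The verdict is "consistent-significant" iff all eight p values are below
    0.05, otherwise "inconsistent" (or "consistent-nonsignificant" when none
    is below 0.05).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InvalidArgumentError("both samples need at least 3 values")
    out: dict[str, float] = {}

    def attempt(name, fn):
        try:
            with np.errstate(all="ignore"):
                out[name] = float(fn())
        except Exception:
            out[name] = float("nan")

    attempt("brunner_munzel", lambda: brunner_munzel(x, y, seed=seed).pvalue)
    attempt("welch_t", lambda: stats.ttest_ind(x, y, equal_var=False).pvalue)
    attempt("student_t", lambda: stats.ttest_ind(x, y, equal_var=True).pvalue)
    attempt("mann_whitney", lambda: stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    attempt("kruskal_wallis", lambda: stats.kruskal(x, y).pvalue)
    attempt("kolmogorov_smirnov", lambda: stats.ks_2samp(x, y).pvalue)
    attempt("mood_median", lambda: stats.median_test(x, y)[1])
    attempt(
        "anderson_darling",
        lambda: stats.anderson_ksamp(
            [x, y],
            variant="midrank",
            method=stats.PermutationMethod(
                n_resamples=ad_resamples, rng=np.random.default_rng(seed)
            ),
        ).pvalue,
    )
    pvals = np.array([out[name] for name in SENSITIVITY_TESTS])
    if np.all(pvals < 0.05):
        verdict = "consistent-significant"
    elif not np.any(pvals < 0.05):
        verdict = "consistent-nonsignificant"
    else:
        verdict = "inconsistent"
    return out, verdict


def sensitivity_grid(data: pd.DataFrame, labels, pair: tuple[int, int],
                     seed: int = 0) -> pd.DataFrame:
    """Per-variable p values of the 8-test battery for one phenotype pair.

    Rows are the columns of ``data`` (one static or kinematic variable each),
    columns the test names — the structure behind a p-value heatmap.
    """
    labels = np.asarray(labels)
    rows = {}
    for offset, variable in enumerate(data.columns):
        values = data[variable].to_numpy(dtype=float)
        x = values[labels == pair[0]]
        y = values[labels == pair[1]]
        pvals, _ = sensitivity_battery(x, y, seed=seed + offset)
        rows[variable] = pvals
    grid = pd.DataFrame(rows).T
    return grid[list(SENSITIVITY_TESTS)]
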