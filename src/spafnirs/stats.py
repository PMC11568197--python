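"""Subgroup-level and between-subgroup inference.

Rank-based tests with rank-biserial effect sizes, Welch's t-test, the
demographic Mann-Whitney battery, the sex-by-subgroup 2x2 contingency suite
(Pearson chi-square without continuity correction, log odds ratio with a
Wald interval, Kendall tau-b from its 2x2 closed form) and Spearman
covariate screening.  No multiple-testing correction is applied by default —
all p-values are reported raw, matching an exploratory single-cohort
analysis; a Benjamini-Hochberg helper is available for sensitivity checks.

Orientation conventions (fixed, so signs are reproducible):

* Mann-Whitney r_rb = 2*U2/(n1*n2) - 1 where U2 counts pairs (with half
  ties) in which the covariate is larger in the SECOND group — positive
  r_rb means the covariate tends to be larger in subgroup 2.
* log OR = ln(bc/ad) on the table rows = subgroup (1, 2), columns =
  (female, male): the log odds of being male in subgroup 1 relative to
  subgroup 2.
* tau-b codes sex female=1/male=0 against subgroup in {1, 2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeResult",
    "ContingencyResult",
    "CorrelationResult",
    "signed_rank_rb",
    "welch_t",
    "mann_whitney_rb",
    "contingency_suite",
    "spearman_screen",
    "table1_battery",
    "benjamini_hochberg",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EffectSizeResult:
    test_name: str
    statistic: float
    p_value: float
    r_rb: float
    ci_low: float
    ci_high: float
    n: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            assert abs(self.r_rb) <= 1 + 1e-12


@dataclass
class ContingencyResult:
    counts: tuple[int, int, int, int]  # a=(sg1,F) b=(sg1,M) c=(sg2,F) d=(sg2,M)
    chi2: float
    df: int
    p: float
    log_or: float
    or_ci_low: float
    or_ci_high: float
    tau_b: float
    tau_z: float
    tau_p: float
    log_or_defined: bool = True


@dataclass
class CorrelationResult:
    pair: str
    spearman_r: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# rank-biserial confidence intervals
# ---------------------------------------------------------------------------

def _fisher_ci(r: float, var0: float) -> tuple[float, float]:
    """Normal approximation on the Fisher z scale with delta-method SE.

    ``var0`` is the null-hypothesis variance of r.  At |r| = 1 the transform
    degenerates and the interval collapses to the point — the behaviour seen
    in reports where fully separated samples carry CI [1.0, 1.0].
    """
    if abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    se = math.sqrt(var0) / (1.0 - r * r)
    return (math.tanh(z - Z95 * se), math.tanh(z + Z95 * se))


# ---------------------------------------------------------------------------
# one-sample signed-rank
# ---------------------------------------------------------------------------

def signed_rank_rb(deltas: np.ndarray, name: str = "signed_rank") -> EffectSizeResult:
    """Wilcoxon signed-rank test of paired differences against zero with the
    matched-pairs rank-biserial effect size r_rb = (T+ - T-)/(T+ + T-).

    Zero differences are dropped (Wilcoxon convention).  All differences
    sharing one sign force r_rb = +/-1 with a degenerate point interval.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return EffectSizeResult(name, float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), (0,), degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    r_rb = (t_plus - t_minus) / (t_plus + t_minus)
    if n < 5:
        # too few pairs for a meaningful test; effect size still reported
        p = float("nan")
    else:
        p = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    var0 = 2.0 * (2 * n + 1) / (3.0 * n * (n + 1))
    lo, hi = _fisher_ci(r_rb, var0)
    return EffectSizeResult(name, min(t_plus, t_minus), p, r_rb, lo, hi, (n,))


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(group1: np.ndarray, group2: np.ndarray) -> dict:
    """Welch's unequal-variance t-test with Satterthwaite df, two-sided."""
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        t = 0.0 if np.mean(x) == np.mean(y) else math.inf
        return {"t": t, "df": float("nan"), "p": float("nan"), "degenerate": True,
                "n": (len(x), len(y))}
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue), "degenerate": False, "n": (len(x), len(y))}


# ---------------------------------------------------------------------------
# two-sample Mann-Whitney with rank-biserial
# ---------------------------------------------------------------------------

def mann_whitney_rb(
    values: np.ndarray, labels: np.ndarray, name: str = "mann_whitney"
) -> EffectSizeResult:
    """Mann-Whitney U (ties counted 1/2) with rank-biserial effect size.

    Groups are the two sorted unique labels.  The reported U is the count of
    pairs in which the second group's value exceeds the first group's (half
    credit for ties); r_rb = 2U/(n1*n2) - 1, positive when the covariate
    tends to be larger in the second group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 label values, got {uniq}")
    g1 = values[labels == uniq[0]]
    g2 = values[labels == uniq[1]]
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("one group is empty")
    # U for group 2 via the rank-sum identity (midranks give half-tie credit)
    ranks = stats.rankdata(np.concatenate([g1, g2]))
    u2 = float(ranks[n1:].sum() - n2 * (n2 + 1) / 2.0)
    r_rb = 2.0 * u2 / (n1 * n2) - 1.0
    p = float(stats.mannwhitneyu(g2, g1, alternative="two-sided").pvalue)
    var0 = (n1 + n2 + 1) / (3.0 * n1 * n2)
    lo, hi = _fisher_ci(r_rb, var0)
    return EffectSizeResult(name, u2, p, r_rb, lo, hi, (n1, n2))


# ---------------------------------------------------------------------------
# 2x2 contingency suite
# ---------------------------------------------------------------------------

def kendall_tau_b_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form tau-b on the 2x2 table, sex coded female=1/male=0 against
    subgroup in {1, 2}: tau_b = (C - D) / sqrt((M - Tx)(M - Ty)) with
    M = N(N-1)/2 and Tx, Ty the tied pair counts of each margin."""
    n = a + b + c + d
    if n < 2:
        return float("nan")
    conc = b * c  # (male, sg1) with (female, sg2): x rises with y
    disc = a * d
    m = n * (n - 1) / 2.0
    nf, nm = a + c, b + d
    n1, n2 = a + b, c + d
    tx = nf * (nf - 1) / 2.0 + nm * (nm - 1) / 2.0
    ty = n1 * (n1 - 1) / 2.0 + n2 * (n2 - 1) / 2.0
    denom = math.sqrt((m - tx) * (m - ty))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def contingency_suite(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Full 2x2 association suite for rows = subgroup (1, 2), columns =
    sex (female, male): counts a=(1,F), b=(1,M), c=(2,F), d=(2,M).

    Pearson chi-square carries no continuity correction.  log OR =
    ln(bc/ad) (odds of male in subgroup 1 vs subgroup 2) with a Wald 95% CI;
    a zero cell leaves log OR undefined (flagged) rather than applying an
    ad-hoc 0.5 correction.  tau-b significance comes from the tie-corrected
    normal approximation on the expanded pair data.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    tau = kendall_tau_b_2x2(a, b, c, d)
    # expanded-data tau for the z / p (tie-corrected asymptotics)
    x = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])  # female=1
    y = np.repeat([1.0, 1.0, 2.0, 2.0], [a, b, c, d])  # subgroup
    if n >= 2 and not (math.isnan(tau)):
        kres = stats.kendalltau(x, y, variant="b")
        tau_p = float(kres.pvalue)
        tau_z = math.copysign(stats.norm.isf(tau_p / 2.0), tau) if tau_p > 0 else math.inf * np.sign(tau)
    else:
        tau_p, tau_z = float("nan"), float("nan")
    defined = min(a, b, c, d) > 0
    if defined:
        log_or = math.log(b * c / (a * d))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = log_or - Z95 * se, log_or + Z95 * se
    else:
        log_or = lo = hi = float("nan")
    return ContingencyResult(
        (a, b, c, d), float(chi2), 1, float(p), log_or, lo, hi,
        tau, tau_z, tau_p, log_or_defined=defined,
    )


# ---------------------------------------------------------------------------
# Spearman covariate screen
# ---------------------------------------------------------------------------

def spearman_screen(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    min_pairs: int = 5,
) -> list[CorrelationResult]:
    """Spearman rho (midrank ties) for each named (x, y) pair of vectors;
    complete cases only, raw p-values.  Constant inputs give a flagged NaN."""
    out = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if len(x) < min_pairs or np.all(x == x[0]) or np.all(y == y[0]):
            out.append(CorrelationResult(name, float("nan"), float("nan"), len(x)))
            continue
        r, p = stats.spearmanr(x, y)
        out.append(CorrelationResult(name, float(r), float(p), len(x)))
    return out


# ---------------------------------------------------------------------------
# Table-1-style covariate battery
# ---------------------------------------------------------------------------

def table1_battery(
    covariates: pd.DataFrame, subgroup: np.ndarray
) -> pd.DataFrame:
    """Run the Mann-Whitney + rank-biserial screen over every covariate
    column against the subgroup labels; returns a tidy table with columns
    (parameter, U, p, r_rb, ci_low, ci_high)."""
    rows = []
    sub = np.asarray(subgroup)
    for col in covariates.columns:
        vals = covariates[col].to_numpy(dtype=float)
        try:
            res = mann_whitney_rb(vals, sub, name=col)
        except ValueError:
            import warnings

            warnings.warn(f"covariate {col!r}: skipped (empty group)")
            continue
        rows.append(
            {
                "parameter": col,
                "U": res.statistic,
                "p": res.p_value,
                "r_rb": res.r_rb,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional sensitivity analysis; never applied by
    default)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
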