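"""Coupling of cerebral oxygenation changes to systemic physiology via a
generalized additive model with a tensor-product smooth.

The model is  dStO2(t) = beta0 + f(dSpO2(t), dPR(t)) + eps  with f a
penalized bivariate spline surface, fitted per optode site and per response
subgroup on time-resolved, baseline-normalized samples pooled across the
subjects of the subgroup.  The link is the identity with Gaussian errors:
the response is a real-valued, approximately symmetric saturation change.

Implementation: penalized regression splines in the P-spline style —
marginal cubic B-spline bases (default 5 functions per margin) combined by
row-wise Kronecker product into a 25-term tensor basis, with second-order
difference penalties on each margin's coefficient direction.  The two
smoothing parameters are chosen by generalized cross-validation (GCV) on a
log-spaced grid; with 25 coefficients each candidate solve is a small dense
system, so the exhaustive grid is cheap and deterministic.

Explained deviance is the Gaussian-deviance analogue of R^2:
100 * (1 - RSS_model / RSS_null).  The smooth term's p-value is an
approximate F-test on the effective degrees of freedom of the penalized fit
(a descriptive screen, as approximate GAM term tests generally are).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "GamConfig",
    "DeltaSeries",
    "GamFitSummary",
    "build_delta_series",
    "fit_gam",
    "partial_effect",
    "classify_partial_effect",
    "compare_subgroups",
]


@dataclass
class GamConfig:
    """Basis and penalty settings for the tensor-product smooth."""

    k_per_margin: int = 5  # marginal basis size (cubic B-splines)
    penalty_order: int = 2  # difference penalty order
    lambda_grid: tuple[float, ...] = tuple(10.0 ** np.arange(-3.0, 7.0))
    grid_size: int = 20  # prediction grid per axis


@dataclass
class DeltaSeries:
    """Pooled complete-case (dStO2, dSpO2, dPR) triples for one site and
    subgroup, with provenance back to (subject, grid index)."""

    site: str  # "ac" | "pfc"
    subgroup: int
    dsto2: np.ndarray
    dspo2: np.ndarray
    dpr: np.ndarray
    subject_ids: np.ndarray  # object array, per triple
    sample_index: np.ndarray  # int array, per triple

    def __len__(self) -> int:
        return len(self.dsto2)


@dataclass
class GamFitSummary:
    site: str
    subgroup: int
    intercept: float
    explained_deviance: float  # percent, 0..100
    term_p: float
    edf: float
    lambdas: tuple[float, float]
    basis: str
    n: int
    grid_dspo2: np.ndarray = field(repr=False)
    grid_dpr: np.ndarray = field(repr=False)
    fitted_surface: np.ndarray = field(repr=False)  # shape (grid, grid)
    coef: np.ndarray = field(repr=False)
    _predict: object = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# series construction
# ---------------------------------------------------------------------------

def build_delta_series(
    normalized: dict[str, dict[str, np.ndarray]],
    members: list[str],
    site: str,
    subgroup: int,
    min_points: int = 50,
) -> DeltaSeries:
    """Pool complete (dStO2, dSpO2, dPR) triples across a subgroup's subjects.

    ``normalized`` maps subject -> signal -> baseline-normalized series on
    the common grid.  Incomplete triples (any missing component) are
    dropped; provenance (subject id, grid index) is kept for every retained
    triple.  At least one member session must contribute ``min_points``
    complete triples.
    """
    sto2_key = f"sto2_{site}"
    rows_sto2, rows_spo2, rows_pr, rows_sid, rows_idx = [], [], [], [], []
    enough = False
    for sid in members:
        sigs = normalized[sid]
        y, xs, xp = sigs[sto2_key], sigs["spo2"], sigs["pr"]
        ok = ~(np.isnan(y) | np.isnan(xs) | np.isnan(xp))
        if ok.sum() >= min_points:
            enough = True
        rows_sto2.append(y[ok])
        rows_spo2.append(xs[ok])
        rows_pr.append(xp[ok])
        rows_sid.append(np.full(ok.sum(), sid, dtype=object))
        rows_idx.append(np.nonzero(ok)[0])
    dsto2 = np.concatenate(rows_sto2) if rows_sto2 else np.empty(0)
    if len(dsto2) == 0 or not enough:
        raise ValueError(
            f"no session with >= {min_points} complete triples for "
            f"site={site} subgroup={subgroup}"
        )
    return DeltaSeries(
        site,
        subgroup,
        dsto2,
        np.concatenate(rows_spo2),
        np.concatenate(rows_pr),
        np.concatenate(rows_sid),
        np.concatenate(rows_idx),
    )


# ---------------------------------------------------------------------------
# spline machinery
# ---------------------------------------------------------------------------

def _bspline_design(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with k basis functions; knots from the
    covariate quantiles, boundary knots clamped at the data range."""
    degree = 3
    n_interior = k - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        raise ValueError("degenerate covariate (constant)")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(
        np.clip(x, lo, hi), knots, degree, extrapolate=False
    ).toarray()
    return design, knots


def _difference_penalty(k: int, order: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def fit_gam(series: DeltaSeries, cfg: GamConfig | None = None) -> GamFitSummary:
    """Fit the penalized tensor-product surface and summarise it.

    Requires >= 50 triples and non-degenerate covariates.  If the tensor
    basis turns out rank-deficient on the data (clustered covariates), the
    marginal basis size is reduced automatically with a warning.
    """
    cfg = cfg or GamConfig()
    n = len(series)
    if n < 50:
        raise ValueError(f"need >= 50 triples, got {n}")
    y = series.dsto2.astype(float)
    k = cfg.k_per_margin
    while True:
        try:
            b1, knots1 = _bspline_design(series.dspo2, k)
            b2, knots2 = _bspline_design(series.dpr, k)
        except ValueError:
            raise ValueError("degenerate covariate; cannot build spline basis")
        bt = _row_kron(b1, b2)
        if k <= 3 or np.linalg.matrix_rank(bt) >= min(bt.shape[1], n) - 2:
            break
        k -= 1
        warnings.warn(f"ill-conditioned tensor basis; reducing k to {k}")

    # identifiability: the tensor basis has unit row sums (partition of
    # unity), so the all-ones coefficient direction duplicates the intercept
    # and sits in the penalty null space.  Project it out: beta = Z @ gamma
    # with Z an orthonormal basis of the complement of span{1}.
    p_raw = bt.shape[1]
    q_full, _ = np.linalg.qr(
        np.column_stack([np.ones((p_raw, 1)) / np.sqrt(p_raw), np.eye(p_raw)[:, :-1]])
    )
    z = q_full[:, 1:]
    col_means = bt.mean(axis=0)
    btc = (bt - col_means) @ z
    p = btc.shape[1]
    s1 = _difference_penalty(k, cfg.penalty_order)
    s2 = _difference_penalty(k, cfg.penalty_order)
    pen1 = z.T @ np.kron(s1, np.eye(k)) @ z
    pen2 = z.T @ np.kron(np.eye(k), s2) @ z

    x_full = np.column_stack([np.ones(n), btc])
    xtx = x_full.T @ x_full
    xty = x_full.T @ y
    rss_null = float(np.sum((y - y.mean()) ** 2))

    def solve(lam1: float, lam2: float):
        pen = np.zeros((p + 1, p + 1))
        pen[1:, 1:] = lam1 * pen1 + lam2 * pen2
        a = xtx + pen + 1e-10 * np.eye(p + 1)
        beta = np.linalg.solve(a, xty)
        # trace of the hat matrix: tr( (XtX+S)^-1 XtX )
        edf = float(np.trace(np.linalg.solve(a, xtx)))
        resid = y - x_full @ beta
        rss = float(resid @ resid)
        return beta, edf, rss

    best = None
    for lam1 in cfg.lambda_grid:
        for lam2 in cfg.lambda_grid:
            beta, edf, rss = solve(lam1, lam2)
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam1, lam2, beta, edf, rss)
    _, lam1, lam2, beta, edf, rss = best

    expl_dev = 100.0 * (1.0 - rss / rss_null) if rss_null > 0 else 0.0
    expl_dev = float(np.clip(expl_dev, 0.0, 100.0))
    edf_smooth = max(edf - 1.0, 0.5)
    df_resid = max(n - edf, 1.0)
    if rss <= 1e-12 * max(rss_null, 1.0):
        term_p = 0.0
    else:
        f_stat = ((rss_null - rss) / edf_smooth) / (rss / df_resid)
        term_p = float(stats.f.sf(max(f_stat, 0.0), edf_smooth, df_resid))

    g1 = np.linspace(series.dspo2.min(), series.dspo2.max(), cfg.grid_size)
    g2 = np.linspace(series.dpr.min(), series.dpr.max(), cfg.grid_size)

    degree = 3

    def predict(xs: np.ndarray, xp: np.ndarray) -> np.ndarray:
        xs = np.clip(xs, series.dspo2.min(), series.dspo2.max())
        xp = np.clip(xp, series.dpr.min(), series.dpr.max())
        d1 = BSpline.design_matrix(xs, knots1, degree, extrapolate=False).toarray()
        d2 = BSpline.design_matrix(xp, knots2, degree, extrapolate=False).toarray()
        dt = (_row_kron(d1, d2) - col_means) @ z
        return beta[0] + dt @ beta[1:]

    gg1, gg2 = np.meshgrid(g1, g2, indexing="ij")
    surface = predict(gg1.ravel(), gg2.ravel()).reshape(cfg.grid_size, cfg.grid_size)

    return GamFitSummary(
        site=series.site,
        subgroup=series.subgroup,
        intercept=float(beta[0]),
        explained_deviance=expl_dev,
        term_p=term_p,
        edf=float(edf),
        lambdas=(float(lam1), float(lam2)),
        basis=f"cubic B-spline tensor {k}x{k}, diff-{cfg.penalty_order} penalty",
        n=n,
        grid_dspo2=g1,
        grid_dpr=g2,
        fitted_surface=surface,
        coef=beta,
        _predict=predict,
    )


# ---------------------------------------------------------------------------
# partial effects and qualitative comparison
# ---------------------------------------------------------------------------

def partial_effect(fit: GamFitSummary, covariate: str) -> np.ndarray:
    """Fitted surface profile along one covariate with the other held at the
    centre of its grid (a partial-dependence slice)."""
    mid = fit.fitted_surface.shape[0] // 2
    if covariate == "dspo2":
        return fit.fitted_surface[:, mid]
    if covariate == "dpr":
        return fit.fitted_surface[mid, :]
    raise ValueError("covariate must be 'dspo2' or 'dpr'")


def classify_partial_effect(
    profile: np.ndarray,
    flat_tol: float = 0.05,
    agreement: float = 0.9,
    central_fraction: float = 0.6,
) -> dict:
    """Classify a partial-effect profile as increasing / decreasing /
    non-monotone / none, with a curvature verdict from second differences
    over the central region.

    ``flat_tol`` is the minimum profile range (response units) below which
    the effect counts as "none"; ``agreement`` the fraction of first
    differences that must share the majority sign for monotone labels.
    """
    d1 = np.diff(profile)
    rng = float(profile.max() - profile.min())
    if rng < flat_tol:
        shape = "none"
        frac = float("nan")
    else:
        pos = float(np.mean(d1 > 0))
        neg = float(np.mean(d1 < 0))
        frac = max(pos, neg)
        if pos >= agreement:
            shape = "increasing"
        elif neg >= agreement:
            shape = "decreasing"
        else:
            shape = "non-monotone"
    m = len(profile)
    lo = int(m * (1 - central_fraction) / 2)
    hi = m - lo
    d2 = np.diff(profile[lo:hi], n=2)
    if len(d2) == 0 or rng < flat_tol:
        curvature = "none"
    elif np.all(d2 < 1e-12):
        curvature = "concave"
    elif np.all(d2 > -1e-12):
        curvature = "convex"
    else:
        curvature = "mixed"
    return {"shape": shape, "sign_agreement": frac, "curvature": curvature,
            "range": rng}


def compare_subgroups(fits: dict[int, GamFitSummary]) -> dict:
    """Qualitative coupling report per subgroup: the monotonicity/curvature
    class of each covariate's partial effect."""
    report: dict = {}
    for g, fit in fits.items():
        report[g] = {
            "site": fit.site,
            "explained_deviance": fit.explained_deviance,
            "term_p": fit.term_p,
            "dspo2": classify_partial_effect(partial_effect(fit, "dspo2")),
            "dpr": classify_partial_effect(partial_effect(fit, "dpr")),
        }
    return report
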