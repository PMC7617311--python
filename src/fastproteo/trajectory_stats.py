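"""Per-protein longitudinal mixed-model testing.

The measurement model for one protein is a random-intercept linear mixed
model over study days,

    y_it = β_0 + Σ_{t∉baseline} β_t·1[day=t] + u_i + ε_it,
    u_i ~ N(0, σ_u²),  ε_it ~ N(0, σ_e²),

fitted by restricted maximum likelihood.  β_t is the change versus the
pre-fast baseline at day t in pre-fast SD units (after `standardize`); the
global "any change" test is a likelihood-ratio χ² of the full model against
the intercept + random-intercept null on ML fits.  Sex-differential response
is tested by a time×sex interaction LRT, and exposure tracks (weight,
3-hydroxybutyrate, ...) are related to protein levels with crossed random
intercepts for participant and day.

The estimation here exploits the single-grouping structure: for a fixed
variance ratio θ = σ_u²/σ_e², GLS estimates and the profiled (RE)ML
log-likelihood are available in closed form via per-participant block
inversion, leaving a one-dimensional optimization in θ.  This makes fitting
thousands of proteins cheap while agreeing with generic mixed-model software
to numerical precision (see the test suite's cross-checks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve_triangular
from scipy.optimize import minimize, minimize_scalar

from .synthetic_data import ProteinMatrix, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryResult",
    "ExposureAssociation",
    "standardize",
    "fit_trajectory",
    "fit_all_trajectories",
    "test_sex_interaction",
    "associate_exposure",
    "associate_exposure_all",
    "adjust_bh",
]

_THETA_MAX = 1e5
_XATOL = 1e-10


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(matrix: ProteinMatrix) -> tuple[ProteinMatrix, list[str]]:
    """Scale every assay by its pre-fast mean and SD.

    The pre-fast pool is all participants' values at the baseline days (a
    single pre-fast sample per participant makes a within-participant SD
    impossible).  After scaling, the pooled pre-fast values of each assay have
    mean 0 and SD 1, so effects read as pre-fast SD units.

    Assays with fewer than two pre-fast values or zero pre-fast variance are
    excluded (returned in the second element) rather than NaN-propagated.
    """
    design = matrix.design
    base_idx = [i for i, t in enumerate(design.timepoints) if t in design.baseline_days]
    base = matrix.values[:, base_idx, :].reshape(-1, len(matrix.assay_ids))
    n_base = np.sum(~np.isnan(base), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(base, axis=0)
        sd = np.nanstd(base, axis=0, ddof=1)
    ok = (n_base >= 2) & np.isfinite(sd) & (sd > 0)
    excluded = [a for a, keep in zip(matrix.assay_ids, ok) if not keep]
    for a in excluded:
        logger.warning("standardize: excluding assay %s (insufficient or constant pre-fast values)", a)
    values = (matrix.values[:, :, ok] - mean[ok]) / sd[ok]
    kept = [a for a, keep in zip(matrix.assay_ids, ok) if keep]
    lod = None
    if matrix.lod is not None:
        lod = (matrix.lod[ok] - mean[ok]) / sd[ok]
    out = ProteinMatrix(design=design, assay_ids=kept, values=values, lod=lod)
    return out, excluded


# ---------------------------------------------------------------------------
# Random-intercept profile likelihood machinery
# ---------------------------------------------------------------------------


class _RandomInterceptFitter:
    """Profiled (RE)ML for y = Xβ + Zu + ε with one random intercept grouping.

    For θ = σ_u²/σ_e², V0 = I + θ·ZZᵀ has the per-group inverse
    I − θ/(1+θ·n_g)·J, so the weighted cross-products needed for GLS are
    rank-one corrections of the OLS cross-products.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        uniq, gidx = np.unique(groups, return_inverse=True)
        self.ng = np.bincount(gidx).astype(float)
        G = len(uniq)
        self.Gx = np.zeros((G, self.p))
        np.add.at(self.Gx, gidx, X)
        self.gy = np.bincount(gidx, weights=y)
        self.Sxx = X.T @ X
        self.Sxy = X.T @ y
        self.Syy = float(y @ y)

    def _crossprods(self, theta: float):
        c = theta / (1.0 + theta * self.ng)
        XtVX = self.Sxx - (self.Gx * c[:, None]).T @ self.Gx
        XtVy = self.Sxy - (self.Gx * c[:, None]).T @ self.gy
        ytVy = self.Syy - float(c @ (self.gy**2))
        return XtVX, XtVy, ytVy

    def gls(self, theta: float):
        XtVX, XtVy, ytVy = self._crossprods(theta)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - float(beta @ XtVy), 1e-300)
        return beta, rss, XtVX

    def neg_loglik(self, theta: float, reml: bool) -> float:
        beta, rss, XtVX = self.gls(theta)
        logdetV0 = float(np.sum(np.log1p(theta * self.ng)))
        if reml:
            df = self.n - self.p
            sig2 = rss / df
            sign, logdetX = np.linalg.slogdet(XtVX)
            return 0.5 * (df * np.log(2 * np.pi * sig2) + logdetV0 + logdetX + df)
        sig2 = rss / self.n
        return 0.5 * (self.n * np.log(2 * np.pi * sig2) + logdetV0 + self.n)

    def fit(self, reml: bool = True):
        """Returns (beta, se, sigma_u2, sigma_e2, loglik, theta)."""
        # Method-of-moments start: between/within decomposition of residuals.
        res = minimize_scalar(
            lambda th: self.neg_loglik(th, reml),
            bounds=(0.0, _THETA_MAX),
            method="bounded",
            options={"xatol": _XATOL, "maxiter": 200},
        )
        theta = float(res.x)
        # The bounded minimizer never lands exactly on 0; snap if the boundary
        # is at least as good.
        if self.neg_loglik(0.0, reml) <= res.fun + 1e-12:
            theta = 0.0
        beta, rss, XtVX = self.gls(theta)
        df = self.n - self.p if reml else self.n
        sig_e2 = rss / df
        cov = sig_e2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))
        ll = -self.neg_loglik(theta, reml)
        return beta, se, theta * sig_e2, sig_e2, ll, theta


def _design_matrix(days: np.ndarray, design: StudyDesign):
    """Intercept + dummies for each non-baseline day (baseline = reference)."""
    nonbase = list(design.nonbaseline_days)
    X = np.ones((len(days), 1 + len(nonbase)))
    for j, t in enumerate(nonbase):
        X[:, 1 + j] = days == t
    return X, nonbase


# ---------------------------------------------------------------------------
# Trajectory fitting
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryResult:
    """Per-protein per-timepoint contrasts and global time test."""

    assay_id: str
    timepoints: list[int]  # non-baseline days
    beta: np.ndarray  # change vs baseline, SD units
    se: np.ndarray
    p_t: np.ndarray
    p_global: float
    sigma_u2: float
    sigma_e2: float
    n_obs: int
    q: float = np.nan
    converged: bool = True
    excluded: bool = False
    reason: str = ""

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "assay_id": self.assay_id,
                "term": "global",
                "beta": np.nan,
                "se": np.nan,
                "p": self.p_global,
                "q": self.q,
                "n_obs": self.n_obs,
            }
        ]
        for t, b, s, p in zip(self.timepoints, self.beta, self.se, self.p_t):
            rows.append(
                {
                    "assay_id": self.assay_id,
                    "term": f"day{t}",
                    "beta": b,
                    "se": s,
                    "p": p,
                    "q": np.nan,
                    "n_obs": self.n_obs,
                }
            )
        return rows


def _long_arrays(y, design: StudyDesign):
    """Accepts an (n_participants, n_timepoints) array or a long DataFrame."""
    if isinstance(y, pd.DataFrame):
        df = y.dropna(subset=["value"])
        days = df["day"].to_numpy()
        vals = df["value"].to_numpy(float)
        parts = df["participant"].to_numpy()
        return vals, days, parts
    y = np.asarray(y, float)
    n_p, n_t = y.shape
    days = np.tile(np.asarray(design.timepoints), n_p)
    parts = np.repeat(np.arange(n_p), n_t)
    vals = y.reshape(-1)
    ok = ~np.isnan(vals)
    return vals[ok], days[ok], parts[ok]


def fit_trajectory(
    y, design: StudyDesign, assay_id: str = "", global_test: str = "f"
) -> TrajectoryResult:
    """Fit the random-intercept timepoint model for one protein.

    Parameters
    ----------
    y : (n_participants, n_timepoints) array (NaN = missing) or a long
        DataFrame with columns participant, day, value.
    global_test : "f" (default) — Wald F on the timepoint-contrast block with
        containment denominator degrees of freedom n − rank(X) − (N−1); for a
        complete balanced design this reproduces the exact repeated-measures
        ANOVA F and is calibrated at small N, where the asymptotic
        likelihood-ratio reference is anti-conservative.  "lrt" —
        likelihood-ratio χ²(T−1) on ML fits of the full vs intercept-only
        model.

    Per-timepoint p-values are Wald tests on the REML fit.
    """
    vals, days, parts = _long_arrays(y, design)
    nonbase = list(design.nonbaseline_days)
    n_obs = len(vals)
    base_parts = set(parts[np.isin(days, list(design.baseline_days))])
    post_parts = set(parts[~np.isin(days, list(design.baseline_days))])
    if len(base_parts & post_parts) < 2:
        return TrajectoryResult(
            assay_id, nonbase, np.full(len(nonbase), np.nan), np.full(len(nonbase), np.nan),
            np.full(len(nonbase), np.nan), np.nan, np.nan, np.nan, n_obs,
            converged=False, excluded=True, reason="fewer than 2 participants with baseline and follow-up",
        )
    X, _ = _design_matrix(days, design)
    if np.var(vals) < 1e-20:
        # constant series: no change at any day, by construction
        return TrajectoryResult(
            assay_id=assay_id, timepoints=nonbase,
            beta=np.zeros(len(nonbase)), se=np.full(len(nonbase), np.nan),
            p_t=np.ones(len(nonbase)), p_global=1.0, sigma_u2=0.0, sigma_e2=0.0,
            n_obs=n_obs,
        )
    fitter = _RandomInterceptFitter(X, vals, parts)
    beta, se, sig_u2, sig_e2, _, theta = fitter.fit(reml=True)
    n_groups = len(np.unique(parts))
    den_df = max(n_obs - X.shape[1] - (n_groups - 1), 1)
    z = np.where(se[1:] > 0, beta[1:] / se[1:], 0.0)
    p_t = 2 * sps.t.sf(np.abs(z), den_df)

    dfree = len(nonbase)
    if global_test == "f":
        # Wald F on the contrast block (correlated through the shared
        # baseline) with containment denominator df; equals the exact
        # repeated-measures ANOVA F when the design is complete and balanced.
        _, rss, XtVX = fitter.gls(theta)
        cov = (rss / (n_obs - X.shape[1])) * np.linalg.inv(XtVX)
        b = beta[1:]
        W = float(b @ np.linalg.solve(cov[1:, 1:], b))
        p_global = float(sps.f.sf(W / dfree, dfree, den_df))
    elif global_test == "lrt":
        _, _, _, _, ll_full, _ = fitter.fit(reml=False)
        null = _RandomInterceptFitter(np.ones((n_obs, 1)), vals, parts)
        _, _, _, _, ll_null, _ = null.fit(reml=False)
        lrt = max(2.0 * (ll_full - ll_null), 0.0)
        p_global = float(sps.chi2.sf(lrt, dfree))
    else:
        raise ValueError("global_test must be 'f' or 'lrt'")

    return TrajectoryResult(
        assay_id=assay_id,
        timepoints=nonbase,
        beta=beta[1:],
        se=se[1:],
        p_t=p_t,
        p_global=p_global,
        sigma_u2=sig_u2,
        sigma_e2=sig_e2,
        n_obs=n_obs,
    )


def fit_all_trajectories(
    matrix: ProteinMatrix, global_test: str = "f"
) -> tuple[list[TrajectoryResult], pd.DataFrame]:
    """Fit every assay; BH-adjust the global p-values as one FDR family.

    Returns the result objects plus a long results table (one `global` row and
    one row per non-baseline day for each assay).
    """
    results = []
    for a, aid in enumerate(matrix.assay_ids):
        res = fit_trajectory(matrix.values[:, :, a], matrix.design, assay_id=aid, global_test=global_test)
        results.append(res)
    valid = [r for r in results if not r.excluded and np.isfinite(r.p_global)]
    if valid:
        qs = adjust_bh(np.array([r.p_global for r in valid]))
        for r, q in zip(valid, qs):
            r.q = float(q)
    rows = [row for r in results for row in r.to_rows()]
    return results, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sex interaction
# ---------------------------------------------------------------------------


def test_sex_interaction(y, design: StudyDesign) -> float:
    """Likelihood-ratio test of a time×sex interaction, χ² with T−1 df.

    Compares the ML fit of timepoint + sex + timepoint:sex against the
    additive timepoint + sex model.  Requires at least two participants of
    each sex.
    """
    vals, days, parts = _long_arrays(y, design)
    if isinstance(y, pd.DataFrame):
        sex_of = dict(zip(design.participant_ids, design.sex))
        if "sex" in y.columns:
            sex_of.update(dict(zip(y["participant"], y["sex"])))
        sexes = np.array([sex_of[p] for p in parts])
    else:
        sexes = np.array([design.sex[p] for p in parts])
    counts = {s: len(np.unique(parts[sexes == s])) for s in ("F", "M")}
    if counts["F"] < 2 or counts["M"] < 2:
        raise ValueError(f"both sexes need >= 2 participants (got {counts})")
    X0, nonbase = _design_matrix(days, design)
    female = (sexes == "F").astype(float)
    X_add = np.column_stack([X0, female])
    inter = X0[:, 1:] * female[:, None]
    X_full = np.column_stack([X_add, inter])
    ll_add = _RandomInterceptFitter(X_add, vals, parts).fit(reml=False)[4]
    ll_full = _RandomInterceptFitter(X_full, vals, parts).fit(reml=False)[4]
    lrt = max(2.0 * (ll_full - ll_add), 0.0)
    return float(sps.chi2.sf(lrt, len(nonbase)))


# ---------------------------------------------------------------------------
# Exposure associations (crossed random intercepts)
# ---------------------------------------------------------------------------


@dataclass
class ExposureAssociation:
    assay_id: str
    exposure: str
    beta: float
    se: float
    p: float
    q: float = np.nan

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.nan


class _CrossedFitter:
    """Profiled ML/REML for two crossed random intercepts.

    V0 = I + θ_a·Z_aZ_aᵀ + θ_b·Z_bZ_bᵀ with participant and timepoint
    groupings.  With U = [Z_a, Z_b] (k = N + T columns) the Woodbury
    identity reduces every solve and determinant to k×k algebra, so the
    two-parameter profile optimization is cheap.
    """

    def __init__(self, X, y, ga, gb):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        Za = pd.get_dummies(ga).to_numpy(float)
        Zb = pd.get_dummies(gb).to_numpy(float)
        self.ka, self.kb = Za.shape[1], Zb.shape[1]
        U = np.hstack([Za, Zb])
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _solve(self, theta):
        k = self.ka + self.kb
        s = np.concatenate([np.full(self.ka, theta[0]), np.full(self.kb, theta[1])])
        shalf = np.sqrt(s)
        A = np.eye(k) + shalf[:, None] * self.UtU * shalf[None, :]
        cho = np.linalg.cholesky(A)
        # V0^{-1}M = M − U·S½·A^{-1}·S½·UᵀM via the precomputed cross-products
        def corr(UtM):
            w = solve_triangular(cho, shalf[:, None] * UtM, lower=True)
            return w
        wX = corr(self.UtX)
        wy = corr(self.Uty[:, None])[:, 0]
        XtVX = self.XtX - wX.T @ wX
        XtVy = self.Xty - wX.T @ wy
        ytVy = self.yty - float(wy @ wy)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - float(beta @ XtVy), 1e-300)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(cho))))
        return beta, rss, XtVX, logdetV0

    def neg_loglik(self, theta, reml=True):
        theta = np.maximum(theta, 0.0)
        beta, rss, XtVX, logdetV0 = self._solve(theta)
        if reml:
            df = self.n - self.p
            sig2 = rss / df
            _, logdetX = np.linalg.slogdet(XtVX)
            return 0.5 * (df * np.log(2 * np.pi * sig2) + logdetV0 + logdetX + df)
        sig2 = rss / self.n
        return 0.5 * (self.n * np.log(2 * np.pi * sig2) + logdetV0 + self.n)

    def fit(self, reml=True):
        res = minimize(
            lambda th: self.neg_loglik(th, reml),
            x0=np.array([0.3, 0.3]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200},
        )
        theta = np.maximum(res.x, 0.0)
        beta, rss, XtVX, _ = self._solve(theta)
        df = self.n - self.p if reml else self.n
        sig_e2 = rss / df
        cov = sig_e2 * np.linalg.inv(XtVX)
        return beta, np.sqrt(np.diag(cov)), theta * sig_e2, sig_e2


def associate_exposure(
    y, exposure: pd.DataFrame, design: StudyDesign, assay_id: str = "", exposure_name: str = "exposure"
) -> ExposureAssociation:
    """Slope of protein level on an exposure with crossed random intercepts.

    Model: y_it = α + γ·x_it + a_i + b_t + ε, a_i and b_t independent random
    intercepts for participant and study day.  `exposure` must give columns
    participant, day and the exposure value (column `exposure_name` or third
    column).  Returns the Wald test of γ.
    """
    vals, days, parts = _long_arrays(y, design)
    col = exposure_name if exposure_name in exposure.columns else exposure.columns[2]
    key = exposure.set_index(["participant", "day"])[col]
    if isinstance(y, pd.DataFrame):
        pid = parts
    else:
        pid = np.array([design.participant_ids[p] for p in parts])
    x = np.array([key.get((p, d), np.nan) for p, d in zip(pid, days)], float)
    ok = ~np.isnan(x)
    vals, days, pid, x = vals[ok], days[ok], pid[ok], x[ok]
    if np.nanstd(x) == 0:
        raise ValueError("constant exposure: slope unidentifiable")
    X = np.column_stack([np.ones_like(x), x])
    beta, se, _, _ = _CrossedFitter(X, vals, pid, days).fit(reml=True)
    zval = beta[1] / se[1] if se[1] > 0 else np.nan
    p = float(2 * sps.norm.sf(abs(zval))) if np.isfinite(zval) else np.nan
    return ExposureAssociation(assay_id=assay_id, exposure=exposure_name, beta=float(beta[1]), se=float(se[1]), p=p)


def associate_exposure_all(
    matrix: ProteinMatrix, exposure: pd.DataFrame, exposure_name: str
) -> pd.DataFrame:
    """One exposure against every assay; BH across assays (one FDR family)."""
    recs = []
    for a, aid in enumerate(matrix.assay_ids):
        try:
            r = associate_exposure(
                matrix.values[:, :, a], exposure, matrix.design, assay_id=aid, exposure_name=exposure_name
            )
        except ValueError:
            continue
        recs.append(r)
    df = pd.DataFrame(
        {
            "assay_id": [r.assay_id for r in recs],
            "exposure": exposure_name,
            "beta": [r.beta for r in recs],
            "se": [r.se for r in recs],
            "p": [r.p for r in recs],
        }
    )
    df["q"] = adjust_bh(df["p"].to_numpy()) if len(df) else []
    df["z"] = df["beta"] / df["se"]
    return df


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j ≥ i} min(1, m·p_(j)/j) on the sorted p-values; the result
    is order-preserving and invariant to the input ordering.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
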