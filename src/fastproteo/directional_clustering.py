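"""Directional clustering of temporal response profiles.

Each significantly changing protein is summarized by its vector of scaled
effect estimates z_t = β_t/SE_t over the non-baseline study days, normalized
to the unit sphere.  Proteins with the same temporal *shape* of response —
regardless of amplitude — then share a direction, and clustering is done with
a mixture of von Mises–Fisher (vMF) distributions augmented with a uniform
"noise" component that absorbs proteins matching no coherent profile:

    p(x) = π_0·U(S^{d−1}) + Σ_k π_k·C_d(κ_k)·exp(κ_k·μ_kᵀx)

fitted by EM with spherical k-means++ initialization and multiple restarts.
The number of clusters is chosen by the first plateau of the Bayesian
Information Criterion over K = 1..k_max, and proteins are hard-assigned to
their maximum-responsibility component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ive, logsumexp

from .synthetic_data import child_rng, SEED_CLUSTER_INIT

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionMatrix",
    "VMFMixtureModel",
    "build_direction_matrix",
    "vmf_log_density",
    "log_uniform_sphere",
    "estimate_kappa",
    "fit_mixture",
    "select_k",
    "assign_hard",
]

KAPPA_MAX = 1e4
RBAR_CAP = 1.0 - 1e-8
NOISE_LABEL = "noise"


# ---------------------------------------------------------------------------
# Direction matrix
# ---------------------------------------------------------------------------


@dataclass
class DirectionMatrix:
    """Unit-norm rows of scaled effect estimates, one row per assay."""

    assay_ids: list[str]
    X: np.ndarray

    def __post_init__(self):
        if self.X.ndim != 2 or self.X.shape[1] < 2:
            raise ValueError("X must be n × d with d >= 2")
        norms = np.linalg.norm(self.X, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("rows of X must have unit norm")

    @property
    def d(self) -> int:
        return self.X.shape[1]


def build_direction_matrix(
    results: pd.DataFrame, q_threshold: float = 0.05
) -> DirectionMatrix:
    """Direction matrix from a trajectory results table.

    Keeps assays whose global q-value passes `q_threshold` (the clustering is
    run on significantly changing proteins only), forms z_t = β_t/SE_t per
    non-baseline day and normalizes each row to unit length.
    """
    glob = results[results["term"] == "global"]
    keep = set(glob.loc[glob["q"] < q_threshold, "assay_id"])
    per_day = results[(results["term"] != "global") & results["assay_id"].isin(keep)].copy()
    if per_day.empty:
        raise ValueError("no assays pass the significance threshold")
    per_day["z"] = per_day["beta"] / per_day["se"]
    wide = per_day.pivot(index="assay_id", columns="term", values="z")
    # preserve chronological day order
    day_cols = sorted(wide.columns, key=lambda c: int(str(c).replace("day", "")))
    wide = wide[day_cols].dropna()
    X = wide.to_numpy(float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    ok = norms[:, 0] > 0
    X = X[ok] / norms[ok]
    return DirectionMatrix(assay_ids=list(wide.index[ok]), X=X)


# ---------------------------------------------------------------------------
# vMF numerics
# ---------------------------------------------------------------------------


def log_uniform_sphere(d: int) -> float:
    """Log density of the uniform distribution on S^{d−1}: Γ(d/2)/(2π^{d/2})."""
    return float(gammaln(d / 2.0) - np.log(2.0) - (d / 2.0) * np.log(np.pi))


def _log_cd(kappa: float, d: int) -> float:
    """log C_d(κ) = log[κ^{d/2−1} / ((2π)^{d/2} I_{d/2−1}(κ))], stable in κ."""
    nu = d / 2.0 - 1.0
    if kappa < 1e-12:
        return log_uniform_sphere(d)
    # log I_ν(κ) = log ive(ν, κ) + κ  (exponentially scaled Bessel)
    log_bessel = np.log(ive(nu, kappa)) + kappa
    return float(nu * np.log(kappa) - (d / 2.0) * np.log(2 * np.pi) - log_bessel)


def vmf_log_density(x: np.ndarray, mu: np.ndarray, kappa: float, d: int | None = None) -> float:
    """Log vMF density at unit vector x: log C_d(κ) + κ·μᵀx.

    At κ = 0 this is the uniform density on the sphere.
    """
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if d is None:
        d = x.shape[-1]
    for v, name in ((x, "x"), (mu, "mu")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a unit vector")
    return _log_cd(kappa, d) + float(kappa * (mu @ x))


def _a_d(kappa: np.ndarray | float, d: int):
    """Mean resultant length A_d(κ) = I_{d/2}(κ)/I_{d/2−1}(κ)."""
    kappa = np.asarray(kappa, float)
    out = np.where(kappa < 1e-12, 0.0, ive(d / 2.0, kappa) / np.maximum(ive(d / 2.0 - 1.0, kappa), 1e-300))
    return out if out.ndim else float(out)


def estimate_kappa(r_bar: float, d: int, refine: bool = True, tol: float = 1e-10) -> float:
    """Concentration from the mean resultant length.

    Banerjee et al.'s closed-form approximation
    κ̂ = r̄(d − r̄²)/(1 − r̄²), optionally refined by Newton iterations on
    A_d(κ) = r̄.  r̄ is capped just below 1 and κ at 1e4 to keep the Bessel
    evaluations finite for degenerate (near-point-mass) clusters.
    """
    if not 0 <= r_bar < 1:
        raise ValueError("r_bar must lie in [0, 1)")
    if r_bar == 0:
        return 0.0
    r = min(r_bar, RBAR_CAP)
    kappa = r * (d - r * r) / (1.0 - r * r)
    if refine:
        for _ in range(50):
            a = _a_d(kappa, d)
            # A'(κ) = 1 − A² − (d−1)/κ · A
            da = 1.0 - a * a - (d - 1.0) / kappa * a
            if abs(da) < 1e-300:
                break
            step = (a - r) / da
            new = kappa - step
            if new <= 0:
                new = kappa / 2.0
            if new > KAPPA_MAX:
                new = KAPPA_MAX
                kappa = new
                break
            if abs(new - kappa) < tol * max(1.0, kappa):
                kappa = new
                break
            kappa = new
    return float(min(kappa, KAPPA_MAX))


# ---------------------------------------------------------------------------
# Mixture model
# ---------------------------------------------------------------------------


@dataclass
class VMFMixtureModel:
    """Fitted noise-augmented vMF mixture.

    Components 0..K−1 are vMF clusters; the last mixture weight belongs to
    the fixed uniform noise component.  `responsibilities` is n × (K+1) with
    the noise column last.
    """

    K: int
    d: int
    mu: np.ndarray  # K × d unit mean directions
    kappa: np.ndarray  # K concentrations
    pi: np.ndarray  # K+1 weights, noise last
    loglik: float
    bic: float
    responsibilities: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def pi_noise(self) -> float:
        return float(self.pi[-1])

    def log_component_matrix(self, X: np.ndarray) -> np.ndarray:
        """n × (K+1) matrix of log π_k + log f_k(x); noise column last."""
        if X.shape[1] != self.d:
            raise ValueError("dimension mismatch between model and data")
        logf = np.empty((X.shape[0], self.K + 1))
        for k in range(self.K):
            logf[:, k] = _log_cd(self.kappa[k], self.d) + self.kappa[k] * (X @ self.mu[k])
        logf[:, -1] = log_uniform_sphere(self.d)
        with np.errstate(divide="ignore"):
            return logf + np.log(np.maximum(self.pi, 1e-300))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "d": self.d,
            "mu": self.mu.tolist(),
            "kappa": self.kappa.tolist(),
            "pi": self.pi.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
        }


def _n_params(K: int, d: int) -> int:
    # K mean directions on the sphere (d−1 each), K concentrations, K free
    # weights (π sums to 1 over K+1 components including the noise weight).
    return K * (d - 1) + K + K


def sample_vmf(mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n vMF(μ, κ) vectors (Wood's rejection sampler on the tangent
    decomposition); κ=0 falls back to uniform sphere draws."""
    mu = np.asarray(mu, float)
    d = len(mu)
    mu = mu / np.linalg.norm(mu)
    if kappa < 1e-12:
        X = rng.standard_normal((n, d))
        return X / np.linalg.norm(X, axis=1, keepdims=True)
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1.0) ** 2)) / (d - 1.0)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1.0) * np.log(1.0 - x0**2)
    ws = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        zz = rng.beta((d - 1.0) / 2.0, (d - 1.0) / 2.0, size=m)
        w = (1.0 - (1.0 + b) * zz) / (1.0 - (1.0 - b) * zz)
        u = rng.random(m)
        ok = kappa * w + (d - 1.0) * np.log(1.0 - x0 * w) - c >= np.log(u)
        k = int(ok.sum())
        ws[filled:filled + k] = w[ok]
        filled += k
    # tangent directions orthogonal to mu
    V = rng.standard_normal((n, d))
    V -= np.outer(V @ mu, mu)
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    X = ws[:, None] * mu[None, :] + np.sqrt(np.maximum(1.0 - ws**2, 0.0))[:, None] * V
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def _kmeanspp_init(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Spherical k-means++ seeding: greedy centers by cosine distance."""
    n = X.shape[0]
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, K):
        dist = np.min(1.0 - X @ np.array(centers).T, axis=1)
        dist = np.maximum(dist, 0.0)
        total = dist.sum()
        if total <= 0:
            centers.append(X[int(rng.integers(n))])
            continue
        probs = dist / total
        centers.append(X[int(rng.choice(n, p=probs))])
    return np.array(centers)


def _em_once(X: np.ndarray, K: int, rng, tol: float, max_iter: int, init=None):
    n, d = X.shape
    if init is None:
        mu = _kmeanspp_init(X, K, rng)
        kappa = np.full(K, 10.0)
        pi = np.full(K + 1, 1.0 / (K + 1))
    else:
        mu, kappa, pi = (a.copy() for a in init)
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    reseeded = np.zeros(K, bool)
    while it < max_iter:
        it += 1
        # E-step
        model = VMFMixtureModel(K, d, mu, kappa, pi, 0.0, 0.0, np.empty((0, 0)), 0, False)
        logw = model.log_component_matrix(X)
        ll = float(np.sum(logsumexp(logw, axis=1)))
        resp = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        trace.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        drop = []
        for k in range(K):
            if np.all(resp[:, k] < 1e-12):
                if not reseeded[k]:  # re-seed once at the point worst-explained
                    reseeded[k] = True
                    worst = int(np.argmin(logsumexp(logw, axis=1)))
                    mu[k] = X[worst]
                    kappa[k] = 10.0
                    resp[:, k] = 1e-8
                    nk[k] = resp[:, k].sum()
                    logger.warning("vMF EM: re-seeded empty component %d", k)
                else:
                    drop.append(k)
        if drop:
            logger.warning("vMF EM: dropping empty components %s", drop)
            keep = [k for k in range(K) if k not in drop]
            mu, kappa = mu[keep], kappa[keep]
            resp = resp[:, keep + [K]]
            resp /= resp.sum(axis=1, keepdims=True)
            K = len(keep)
            reseeded = reseeded[keep]
            pi = resp.mean(axis=0)
            nk = resp.sum(axis=0)
            prev_ll = -np.inf
            if K == 0:
                break
        resultant = resp[:, :K].T @ X  # K × d
        rnorm = np.linalg.norm(resultant, axis=1)
        for k in range(K):
            if rnorm[k] > 0 and nk[k] > 0:
                mu[k] = resultant[k] / rnorm[k]
                rbar = min(rnorm[k] / nk[k], RBAR_CAP)
                kappa[k] = estimate_kappa(rbar, d, refine=False)
        pi = resp.mean(axis=0)
    model = VMFMixtureModel(
        K, d, mu, kappa, pi, prev_ll, -2.0 * prev_ll + _n_params(K, d) * np.log(n),
        resp, it, converged, trace,
    )
    return model


def fit_mixture(
    X, K: int, seed: int = 0, tol: float = 1e-8, max_iter: int = 500, n_init: int = 10
) -> VMFMixtureModel:
    """EM fit of the K-cluster vMF mixture with a fixed uniform noise component.

    Runs `n_init` restarts with spherical k-means++ seeding from child seeds
    of `seed` and returns the best fit by log-likelihood.
    """
    if isinstance(X, DirectionMatrix):
        X = X.X
    X = np.asarray(X, float)
    n = X.shape[0]
    if not n > K >= 1:
        raise ValueError("need n > K >= 1")
    best = None
    for i in range(n_init):
        rng = child_rng(seed * 1000 + i, SEED_CLUSTER_INIT)
        model = _em_once(X.copy(), K, rng, tol, max_iter)
        if best is None or model.loglik > best.loglik:
            best = model
    return best


def select_k(
    X,
    k_max: int = 20,
    plateau_tol: float = 0.005,
    seed: int = 0,
    n_init_scan: int = 10,
    n_init_final: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[int, dict[int, VMFMixtureModel]]:
    """Choose the cluster count by the first BIC plateau.

    Fits K = 1..k_max (restart-limited scan), computes BIC_K, and picks the
    smallest K with (BIC_K − BIC_{K+1}) / |BIC_K| < plateau_tol — i.e. the
    point where adding a cluster no longer improves the fit appreciably.  The
    selected K is then refitted with the full number of restarts (mirroring a
    scan-then-refit workflow); the whole BIC curve is returned for inspection.
    """
    if isinstance(X, DirectionMatrix):
        X = X.X
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_hi = min(k_max, X.shape[0] - 1)
    models: dict[int, VMFMixtureModel] = {}
    for K in range(1, k_hi + 1):
        best = fit_mixture(X, K, seed=seed, tol=tol, max_iter=max_iter, n_init=n_init_scan)
        if K > 1 and models[K - 1].K == K - 1:
            # warm start: grow the previous solution by one component seeded
            # at the worst-explained point, guarding the scan against
            # restart-to-restart optimization noise in the BIC curve
            prev = models[K - 1]
            logw = prev.log_component_matrix(X)
            worst = int(np.argmin(logsumexp(logw, axis=1)))
            mu0 = np.vstack([prev.mu, X[worst]])
            kappa0 = np.append(prev.kappa, 30.0)
            pi0 = np.append(prev.pi[:-1] * (1 - 1.0 / (K + 1)), [1.0 / (2 * (K + 1)), prev.pi[-1]])
            pi0 /= pi0.sum()
            rng = child_rng(seed, SEED_CLUSTER_INIT)
            warm = _em_once(X.copy(), K, rng, tol, max_iter, init=(mu0, kappa0, pi0))
            if warm.K == K and warm.loglik > best.loglik:
                best = warm
        models[K] = best
    k_star = k_hi
    for K in range(1, k_hi):
        b0, b1 = models[K].bic, models[K + 1].bic
        if (b0 - b1) / max(abs(b0), 1e-300) < plateau_tol:
            k_star = K
            break
    if n_init_final > n_init_scan:
        refit = fit_mixture(X, k_star, seed=seed, tol=tol, max_iter=max_iter, n_init=n_init_final)
        if refit.K == k_star and refit.loglik > models[k_star].loglik:
            models[k_star] = refit
    return k_star, models


def assign_hard(model: VMFMixtureModel, X) -> dict[str, int | str]:
    """Hard assignment: maximum-responsibility component per row.

    Returns assay_id → cluster label (1..K) or "noise".  Ties break to the
    lowest component index (noise is last).  When `X` is a raw array the keys
    are row indices as strings.
    """
    if isinstance(X, DirectionMatrix):
        ids, arr = X.assay_ids, X.X
    else:
        arr = np.asarray(X, float)
        ids = [str(i) for i in range(arr.shape[0])]
    logw = model.log_component_matrix(arr)
    labels = np.argmax(logw, axis=1)  # first maximum wins
    out: dict[str, int | str] = {}
    for aid, lab in zip(ids, labels):
        out[aid] = NOISE_LABEL if lab == model.K else int(lab) + 1
    return out
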