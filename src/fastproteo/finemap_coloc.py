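"""Summary-statistics fine-mapping and colocalization.

Cis regions (protein-coding gene ± 500 kb, excluding the extended MHC) are
fine-mapped with a sum-of-single-effects (SuSiE-style) regression on
z-scores:  z ~ N(Rb, R) with b = Σ_l γ_l β_l, each single effect l placing
all of its mass on one variant.  The variational fit yields per-effect
inclusion probabilities α_l, 95% credible sets with LD purity, and
per-variant posterior inclusion probabilities PIP_j = 1 − Π_l(1 − α_lj).
Because summary-statistic fits can produce correlated credible sets, the
number of effects L is scanned from 2 to 10 and the fit with the largest
collection of mutually independent credible-set leads (pairwise r² < 0.25)
is carried forward.

Colocalization of a protein with an outcome uses the five-hypothesis
enumeration over Wakefield approximate Bayes factors (H0 no signal, H1/H2
one trait only, H3 two distinct variants, H4 one shared variant) with priors
p1 = p2 = 1e−4 and a conservative shared prior p12 = 5e−6, both region-wide
and per credible-set pair (fine-mapping before colocalization).  A
protein–trait link is accepted when PP(H4) ≥ 80% and the shared lead variant
is a credible-set lead cis-pQTL or a strong proxy (r² > 0.8); accepted links
form a signed bipartite protein–trait network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "CisRegion",
    "SusieFit",
    "CredibleSet",
    "ColocResult",
    "ProteinTraitEdge",
    "extract_cis_region",
    "susie_rss",
    "credible_sets",
    "select_L",
    "finemap_region",
    "wakefield_labf",
    "coloc_abf",
    "coloc_credible_pairs",
    "accept_link",
    "build_network",
    "align_alleles",
    "MHC_REGION",
]

MHC_REGION = ("6", 25_500_000, 34_000_000)
CIS_WINDOW = 500_000
DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 5e-6}
# Conventional Wakefield prior SDs for the effect: quantitative traits 0.15,
# binary (log-odds) traits 0.2.
W_QUANT = 0.15**2
W_BINARY = 0.2**2


# ---------------------------------------------------------------------------
# Cis regions and allele alignment
# ---------------------------------------------------------------------------


@dataclass
class CisRegion:
    gene: str
    chrom: str
    start: int  # window start (1-based, inclusive)
    end: int
    variants: pd.DataFrame  # summary-stat rows within the window


def extract_cis_region(
    gene: str,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    variants: pd.DataFrame,
    window: int = CIS_WINDOW,
) -> CisRegion | None:
    """Variants within gene boundaries ± `window`, minus the extended MHC.

    `variants` needs columns chr and pos (1-based).  Returns None (with a log
    entry) when no variant survives filtering.
    """
    lo = max(gene_start - window, 1)
    hi = gene_end + window
    chrom = str(gene_chrom).removeprefix("chr")
    v = variants[(variants["chr"].astype(str).str.removeprefix("chr") == chrom)
                 & (variants["pos"] >= lo) & (variants["pos"] <= hi)].copy()
    mhc_chrom, mhc_lo, mhc_hi = MHC_REGION
    if chrom == mhc_chrom:
        v = v[(v["pos"] < mhc_lo) | (v["pos"] > mhc_hi)]
    if v.empty:
        logger.warning("extract_cis_region: %s has no variants after filtering, skipped", gene)
        return None
    return CisRegion(gene=gene, chrom=chrom, start=lo, end=hi, variants=v.reset_index(drop=True))


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def align_alleles(df1: pd.DataFrame, df2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Align trait 2's effect alleles to trait 1's on the shared variant panel.

    Matches on variant_id; flips beta/eaf where (effect, other) are swapped
    (including strand flips); drops strand-ambiguous A/T and C/G variants and
    unmatched allele pairs with a logged count.  Returns the two aligned
    frames and the number of dropped variants.
    """
    m = df1.merge(df2, on="variant_id", suffixes=("_1", "_2"))
    keep, flip = [], []
    dropped = 0
    for i, r in m.iterrows():
        e1, o1 = r["effect_allele_1"], r["other_allele_1"]
        e2, o2 = r["effect_allele_2"], r["other_allele_2"]
        if {e1, o1} in ({"A", "T"}, {"C", "G"}):
            dropped += 1
            continue
        ce2, co2 = _COMPLEMENT.get(e2, "?"), _COMPLEMENT.get(o2, "?")
        if (e2, o2) == (e1, o1) or (ce2, co2) == (e1, o1):
            keep.append(i)
            flip.append(False)
        elif (o2, e2) == (e1, o1) or (co2, ce2) == (e1, o1):
            keep.append(i)
            flip.append(True)
        else:
            dropped += 1
    if dropped:
        logger.warning("align_alleles: dropped %d ambiguous/mismatched variants", dropped)
    m = m.loc[keep].reset_index(drop=True)
    flip = np.array(flip, bool)
    out1 = pd.DataFrame({
        "variant_id": m["variant_id"], "beta": m["beta_1"], "se": m["se_1"],
        "n": m.get("n_1"), "eaf": m.get("eaf_1"),
        "effect_allele": m["effect_allele_1"], "other_allele": m["other_allele_1"],
    })
    beta2 = np.where(flip, -m["beta_2"], m["beta_2"])
    eaf2 = m.get("eaf_2")
    if eaf2 is not None:
        eaf2 = np.where(flip, 1.0 - eaf2, eaf2)
    out2 = pd.DataFrame({
        "variant_id": m["variant_id"], "beta": beta2, "se": m["se_2"],
        "n": m.get("n_2"), "eaf": eaf2,
        "effect_allele": m["effect_allele_1"], "other_allele": m["other_allele_1"],
    })
    return out1, out2, dropped


# ---------------------------------------------------------------------------
# SuSiE-RSS
# ---------------------------------------------------------------------------


@dataclass
class SusieFit:
    """Sum-of-single-effects fit on z-scores."""

    L: int
    alpha: np.ndarray  # L × M inclusion probabilities (each row sums to 1)
    mu: np.ndarray  # L × M posterior means given inclusion
    mu2: np.ndarray  # L × M posterior second moments given inclusion
    lbf_variable: np.ndarray  # L × M per-variant log Bayes factors
    lbf: np.ndarray  # L per-effect total log Bayes factor
    V: np.ndarray  # L prior effect variances
    elbo: list[float]
    converged: bool

    @property
    def pip(self) -> np.ndarray:
        """PIP_j = 1 − Π_l (1 − α_lj), over effects with nonzero prior variance."""
        active = self.V > 0
        if not active.any():
            return np.zeros(self.alpha.shape[1])
        return 1.0 - np.prod(1.0 - self.alpha[active], axis=0)


def _check_R(R: np.ndarray, tol: float = 1e-8) -> None:
    M = R.shape[0]
    if R.shape != (M, M):
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    w = np.linalg.eigvalsh(R)
    if w.min() < -tol * max(w.max(), 1.0):
        raise ValueError(
            "R is not positive semi-definite within tolerance; "
            "regularize, e.g. R + 1e-8*I"
        )


def _ser_update(zr: np.ndarray, V: float, prior: np.ndarray):
    """Single-effect regression on residual z-scores (unit-variance obs)."""
    if V <= 0:
        M = len(zr)
        return prior.copy(), np.zeros(M), np.zeros(M), np.zeros(M), 0.0
    s2 = V / (1.0 + V)
    lbf = 0.5 * np.log(1.0 / (1.0 + V)) + 0.5 * zr**2 * s2
    logw = lbf + np.log(prior)
    lbf_total = float(logsumexp(logw))
    alpha = np.exp(logw - lbf_total)
    mu = s2 * zr
    mu2 = mu**2 + s2
    return alpha, mu, mu2, lbf, lbf_total


def _optimize_V(zr: np.ndarray, prior: np.ndarray, v_max: float = 1e4) -> float:
    """Prior effect variance maximizing the single-effect Bayes factor."""

    def neg(lv):
        V = np.exp(lv)
        s2 = V / (1.0 + V)
        lbf = 0.5 * np.log(1.0 / (1.0 + V)) + 0.5 * zr**2 * s2
        return -float(logsumexp(lbf + np.log(prior)))

    res = minimize_scalar(neg, bounds=(-10.0, np.log(v_max)), method="bounded",
                          options={"xatol": 1e-6})
    # A null effect (all-noise residual) is better explained by V = 0, where
    # the Bayes factor is exactly 1.
    if -res.fun <= 0.0:
        return 0.0
    return float(np.exp(res.x))


def susie_rss(
    z: np.ndarray,
    R: np.ndarray,
    n: int | None = None,
    L: int = 10,
    prior_variance: float = 50.0,
    estimate_prior_variance: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
    prior_weights: np.ndarray | None = None,
) -> SusieFit:
    """Fit the sum-of-single-effects model to marginal z-scores and LD.

    Iterative Bayesian stepwise selection: each effect is refit on the
    residual z-vector obtained by removing the other effects' expected
    contributions through R.  Per-variant Bayes factors under a N(0, σ0²)
    effect prior give the inclusion probabilities α_l; σ0² is optimized per
    effect when `estimate_prior_variance` (a null effect collapses to σ0²=0).
    Convergence is declared when the relative ELBO change drops below `tol`.
    """
    z = np.asarray(z, float)
    M = len(z)
    _check_R(np.asarray(R, float))
    R = np.asarray(R, float)
    prior = np.full(M, 1.0 / M) if prior_weights is None else np.asarray(prior_weights, float)
    prior = prior / prior.sum()

    alpha = np.full((L, M), 1.0 / M)
    mu = np.zeros((L, M))
    mu2 = np.zeros((L, M))
    lbf_var = np.zeros((L, M))
    lbf = np.zeros(L)
    V = np.full(L, float(prior_variance))
    b_l = alpha * mu  # L × M expected effect per layer
    Rb = R @ b_l.sum(axis=0)
    elbo_trace: list[float] = []
    converged = False

    def _elbo() -> float:
        b_bar = b_l.sum(axis=0)
        fit_term = float(b_bar @ z)
        quad = float(b_bar @ (R @ b_bar))
        quad -= sum(float(b_l[l] @ (R @ b_l[l])) for l in range(L))
        quad += float(np.sum(alpha * mu2))
        kl = 0.0
        for l in range(L):
            if V[l] <= 0:
                continue
            a = alpha[l]
            nz = a > 0
            s2 = V[l] / (1.0 + V[l])
            kl_gauss = 0.5 * (np.log(V[l] / s2) + (mu2[l][nz]) / V[l] - 1.0)
            kl += float(np.sum(a[nz] * (np.log(a[nz] / prior[nz]) + kl_gauss)))
        return fit_term - 0.5 * quad - kl

    for it in range(max_iter):
        for l in range(L):
            Rb -= R @ b_l[l]
            zr = z - Rb
            if estimate_prior_variance:
                V[l] = _optimize_V(zr, prior)
            alpha[l], mu[l], mu2[l], lbf_var[l], lbf[l] = _ser_update(zr, V[l], prior)
            b_l[l] = alpha[l] * mu[l]
            Rb += R @ b_l[l]
        e = _elbo()
        elbo_trace.append(e)
        if it > 0 and abs(e - elbo_trace[-2]) < tol * (1.0 + abs(e)):
            converged = True
            break
    if not converged:
        logger.warning("susie_rss: no ELBO convergence after %d iterations", max_iter)
    return SusieFit(L=L, alpha=alpha, mu=mu, mu2=mu2, lbf_variable=lbf_var,
                    lbf=lbf, V=V, elbo=elbo_trace, converged=converged)


# ---------------------------------------------------------------------------
# Credible sets
# ---------------------------------------------------------------------------


@dataclass
class CredibleSet:
    effect: int  # index of the single effect within the fit
    members: tuple[int, ...]  # variant indices, descending α
    lead: int  # max-α member
    coverage: float  # attained cumulative α
    purity: float  # min |r| within the set

    def __contains__(self, j: int) -> bool:
        return j in self.members


def credible_sets(
    fit: SusieFit,
    R: np.ndarray,
    coverage: float = 0.95,
    min_purity: float = 0.5,
) -> list[CredibleSet]:
    """Level-`coverage` credible set per active effect, purity-filtered.

    For each effect: rank variants by α and take the smallest prefix whose
    cumulative α reaches `coverage`; purity is the minimum |r| among members
    (1 for singletons).  Sets failing `min_purity` are dropped, and identical
    member sets from different effects are deduplicated (first effect kept).
    """
    R = np.asarray(R, float)
    out: list[CredibleSet] = []
    seen: set[tuple[int, ...]] = set()
    for l in range(fit.L):
        if fit.V[l] <= 0:
            continue
        order = np.argsort(-fit.alpha[l], kind="mergesort")
        csum = np.cumsum(fit.alpha[l][order])
        k = int(np.searchsorted(csum, coverage) + 1)
        k = min(k, len(order))
        members = tuple(int(j) for j in order[:k])
        attained = float(csum[k - 1])
        if attained < coverage - 1e-12:
            continue  # diffuse effect: no valid set at this coverage
        key = tuple(sorted(members))
        if key in seen:
            continue
        sub = np.abs(R[np.ix_(members, members)])
        purity = 1.0 if len(members) == 1 else float(np.min(sub[np.triu_indices(len(members), k=1)]))
        if purity < min_purity:
            continue
        seen.add(key)
        out.append(CredibleSet(effect=l, members=members, lead=members[0],
                               coverage=attained, purity=purity))
    return out


def _max_independent_leads(sets: list[CredibleSet], R: np.ndarray, r2_max: float = 0.25) -> int:
    """Size of the largest subset of credible-set leads with pairwise r² < r2_max."""
    leads = [cs.lead for cs in sets]
    k = len(leads)
    if k <= 1:
        return k
    r2 = np.asarray(R)[np.ix_(leads, leads)] ** 2
    best = 1
    for mask in range(1, 1 << k):
        idx = [i for i in range(k) if mask >> i & 1]
        if len(idx) <= best:
            continue
        sub = r2[np.ix_(idx, idx)]
        if np.all(sub[np.triu_indices(len(idx), k=1)] < r2_max):
            best = len(idx)
    return best


def select_L(
    fits: dict[int, SusieFit],
    R: np.ndarray,
    r2_max: float = 0.25,
    coverage: float = 0.95,
    min_purity: float = 0.5,
) -> tuple[SusieFit, list[CredibleSet]]:
    """Pick the fit whose credible sets give the most independent lead pQTLs.

    For each candidate L, credible sets are deduplicated and counted by the
    largest subset of leads with pairwise r² < `r2_max`; the fit maximizing
    that count wins, ties to the smallest L.  Raises when every fit failed.
    """
    converged = {L: f for L, f in fits.items() if f is not None}
    if not converged:
        raise ValueError("all fine-mapping fits failed for this region")
    best_L, best_count, best_sets = None, -1, []
    for L in sorted(converged):
        sets = credible_sets(converged[L], R, coverage=coverage, min_purity=min_purity)
        count = _max_independent_leads(sets, R, r2_max=r2_max)
        if count > best_count:
            best_L, best_count, best_sets = L, count, sets
    return converged[best_L], best_sets


def finemap_region(
    z: np.ndarray,
    R: np.ndarray,
    n: int | None = None,
    L_range: tuple[int, int] = (2, 10),
    **kwargs,
) -> tuple[SusieFit, list[CredibleSet]]:
    """Fit every L in `L_range` and apply the independence-selection rule."""
    fits = {}
    for L in range(L_range[0], L_range[1] + 1):
        try:
            fits[L] = susie_rss(z, R, n=n, L=L, **kwargs)
        except ValueError:
            raise
    return select_L(fits, R)


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------


def wakefield_labf(beta: float, se: float, W: float):
    """Wakefield log approximate Bayes factor against the point null.

    lABF = ½·log(V/(V+W)) + z²·W / (2(V+W)) with V = se², z = beta/se.
    Vectorizes over beta/se arrays.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if W < 0:
        raise ValueError("W must be >= 0")
    V = se**2
    z2 = (beta / se) ** 2
    out = 0.5 * np.log(V / (V + W)) + 0.5 * z2 * W / (V + W)
    return out if out.ndim else float(out)


@dataclass
class ColocResult:
    pp: np.ndarray  # PP(H0..H4)
    priors: dict[str, float]
    per_variant_h4: np.ndarray  # posterior over the shared variant under H4
    lead: int  # index of the most probable shared variant
    variant_ids: list[str] | None = None
    provenance: str = "region-ABF"
    cs_pair: tuple[int, int] | None = None

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def lead_variant(self) -> str | int:
        return self.variant_ids[self.lead] if self.variant_ids else self.lead


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a ≥ b; −inf when the difference vanishes."""
    if b >= a - 1e-12:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def _coloc_from_labf(
    l1: np.ndarray, l2: np.ndarray, p1: float, p2: float, p12: float,
    variant_ids=None, provenance="region-ABF", cs_pair=None,
) -> ColocResult:
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + _logdiff(s1 + s2, s12),
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    joint = l1 + l2
    per_variant = np.exp(joint - logsumexp(joint))
    lead = int(np.argmax(per_variant))
    return ColocResult(pp=pp, priors={"p1": p1, "p2": p2, "p12": p12},
                       per_variant_h4=per_variant, lead=lead,
                       variant_ids=list(variant_ids) if variant_ids is not None else None,
                       provenance=provenance, cs_pair=cs_pair)


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = DEFAULT_PRIORS["p1"],
    p2: float = DEFAULT_PRIORS["p2"],
    p12: float = DEFAULT_PRIORS["p12"],
    W1: float = W_QUANT,
    W2: float = W_QUANT,
    aligned: bool = False,
) -> ColocResult:
    """Region-level enumeration colocalization from two aligned stat frames.

    Frames need columns variant_id, beta, se (plus alleles unless
    `aligned=True`).  Per-variant Wakefield lABFs feed the standard
    five-hypothesis sums (a single-causal-per-trait assumption); PP(H0..H4)
    are returned together with the per-variant posterior for the shared
    variant under H4.
    """
    if not aligned:
        stats1, stats2, _ = align_alleles(stats1, stats2)
    else:
        if list(stats1["variant_id"]) != list(stats2["variant_id"]):
            raise ValueError("misaligned variant panels")
    if len(stats1) == 0:
        raise ValueError("no shared variants")
    l1 = wakefield_labf(stats1["beta"].to_numpy(), stats1["se"].to_numpy(), W1)
    l2 = wakefield_labf(stats2["beta"].to_numpy(), stats2["se"].to_numpy(), W2)
    return _coloc_from_labf(np.atleast_1d(l1), np.atleast_1d(l2), p1, p2, p12,
                            variant_ids=stats1["variant_id"])


def coloc_credible_pairs(
    fit1: SusieFit,
    fit2: SusieFit,
    R: np.ndarray,
    sets1: list[CredibleSet] | None = None,
    sets2: list[CredibleSet] | None = None,
    p1: float = DEFAULT_PRIORS["p1"],
    p2: float = DEFAULT_PRIORS["p2"],
    p12: float = DEFAULT_PRIORS["p12"],
    variant_ids=None,
    coverage: float = 0.95,
    min_purity: float = 0.5,
) -> list[ColocResult]:
    """Fine-mapping-before-colocalization: one test per credible-set pair.

    For every (trait-1 credible set) × (trait-2 credible set) combination the
    five-hypothesis computation is run on that pair of single-effect
    log Bayes factors, so multiple causal variants per region are handled.
    Returns an empty list when either fit has no credible set.
    """
    if sets1 is None:
        sets1 = credible_sets(fit1, R, coverage=coverage, min_purity=min_purity)
    if sets2 is None:
        sets2 = credible_sets(fit2, R, coverage=coverage, min_purity=min_purity)
    out: list[ColocResult] = []
    for cs1 in sets1:
        for cs2 in sets2:
            res = _coloc_from_labf(
                fit1.lbf_variable[cs1.effect], fit2.lbf_variable[cs2.effect],
                p1, p2, p12, variant_ids=variant_ids,
                provenance="credible-set-pair", cs_pair=(cs1.effect, cs2.effect),
            )
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# Link acceptance and network
# ---------------------------------------------------------------------------


def accept_link(
    coloc: ColocResult,
    pqtl_sets: list[CredibleSet],
    R: np.ndarray,
    pp4_min: float = 0.80,
    r2_proxy: float = 0.8,
) -> bool:
    """Shared-signal rule: PP4 ≥ 80% and the shared lead is a credible-set
    lead cis-pQTL or a strong proxy of one (r² > 0.8)."""
    j = coloc.lead
    R = np.asarray(R)
    if not 0 <= j < R.shape[0]:
        raise ValueError("lead shared variant absent from the LD panel")
    if coloc.pp4 < pp4_min:
        return False
    for cs in pqtl_sets:
        if j == cs.lead or R[j, cs.lead] ** 2 > r2_proxy:
            return True
    return False


@dataclass
class ProteinTraitEdge:
    """Accepted genetically shared protein–trait link.

    `beta_protein` and `beta_trait` are the per-allele effects at the shared
    variant, aligned to the same effect allele, so the sign is invariant to
    relabeling alleles (negating both betas leaves it unchanged).
    """

    protein: str
    trait: str
    pp4: float
    variant: str
    beta_protein: float
    beta_trait: float
    provenance: str = "credible-set-pair"

    @property
    def sign(self) -> str:
        return "concordant" if np.sign(self.beta_protein) == np.sign(self.beta_trait) else "discordant"


def build_network(links: list[ProteinTraitEdge]) -> nx.Graph:
    """Bipartite protein–trait graph from accepted links.

    Node attribute `bipartite` is 0 for proteins, 1 for traits; edges carry
    PP4, the shared variant, and the concordant/discordant sign.  Duplicate
    protein–trait pairs keep the highest-PP4 link (logged).
    """
    best: dict[tuple[str, str], ProteinTraitEdge] = {}
    for e in links:
        key = (e.protein, e.trait)
        if key in best:
            logger.warning("build_network: duplicate link %s-%s, keeping higher PP4", *key)
            if e.pp4 <= best[key].pp4:
                continue
        best[key] = e
    G = nx.Graph()
    for (protein, trait), e in best.items():
        G.add_node(protein, bipartite=0, kind="protein")
        G.add_node(trait, bipartite=1, kind="trait")
        G.add_edge(protein, trait, pp4=e.pp4, variant=e.variant, sign=e.sign,
                   beta_protein=e.beta_protein, beta_trait=e.beta_trait,
                   provenance=e.provenance)
    return G


def write_network(G: nx.Graph, edge_tsv, graphml) -> None:
    rows = [
        {"protein": u if G.nodes[u]["bipartite"] == 0 else v,
         "trait": v if G.nodes[u]["bipartite"] == 0 else u,
         **data}
        for u, v, data in G.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(edge_tsv, sep="\t", index=False)
    nx.write_graphml(G, graphml)
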