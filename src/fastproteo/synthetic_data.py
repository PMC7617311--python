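"""Synthetic study generator for prolonged-fasting proteomics analyses.

Everything downstream of this module (mixed-model trajectory testing,
directional clustering, enrichment, fine-mapping/colocalization) is exercised
on data produced here, with known ground truth:

* a longitudinal plasma-proteomics study — 12 participants sampled at a
  pre-fast baseline (day −2), daily during a 7-day water-only fast, and after
  a refeed (day 10), with protein values on a relative log2-like scale;
* physiological exposure tracks (weight decline and a 3-hydroxybutyrate rise);
* gene-set (GMT) and tissue/cell-type specificity annotation fixtures;
* GWAS summary-statistic regions with a realistic LD structure, simulated
  under each of the five colocalization hypotheses H0–H4.

All generators are deterministic given an integer seed.  Child seeds for the
individual generators are derived from the one global seed with fixed offsets
so that the components can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "ProteinMatrix",
    "SimulationTruth",
    "SimConfig",
    "ExposureConfig",
    "GwasRegion",
    "ARCHETYPE_NAMES",
    "archetype_curve",
    "generate_study",
    "generate_exposures",
    "generate_gwas_region",
    "generate_genesets",
    "generate_tissue_annotation",
    "make_ld_matrix",
    "child_rng",
]

# Fixed child-seed offsets (one global seed; components draw independent streams).
SEED_STUDY = 0
SEED_EXPOSURES = 1
SEED_GWAS = 2
SEED_GENESETS = 3
SEED_ANNOTATION = 4
SEED_CLUSTER_INIT = 5


def child_rng(seed: int, offset: int) -> np.random.Generator:
    """Deterministic child generator for component `offset` of global `seed`."""
    return np.random.default_rng([int(offset), int(seed)])


# ---------------------------------------------------------------------------
# Study design and containers
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS = (-2, 1, 2, 3, 4, 5, 6, 7, 10)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the fasting study.

    Days are study days: negative = pre-fast baseline, 1..7 = fasting days,
    day 10 = three days after refeeding started.
    """

    participant_ids: tuple[str, ...]
    sex: tuple[str, ...]  # per participant, "F" or "M"
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    baseline_days: frozenset[int] = frozenset({-2})
    fasting_days: frozenset[int] = frozenset(range(1, 8))

    def __post_init__(self):
        if len(self.participant_ids) != len(self.sex):
            raise ValueError("sex must be given per participant")
        if any(s not in ("F", "M") for s in self.sex):
            raise ValueError("sex labels must be 'F' or 'M'")
        tp = tuple(self.timepoints)
        if list(tp) != sorted(set(tp)):
            raise ValueError("timepoints must be strictly increasing")
        if not self.baseline_days:
            raise ValueError("baseline_days must be nonempty")
        if self.baseline_days & self.fasting_days:
            raise ValueError("baseline_days and fasting_days must be disjoint")
        if not self.baseline_days <= set(tp):
            raise ValueError("baseline_days must be sampled timepoints")

    @classmethod
    def default(cls, n_participants: int = 12, n_female: int = 5) -> "StudyDesign":
        """The study's layout: 12 volunteers (5 women, 7 men), 9 sampling days."""
        if n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0 <= n_female <= n_participants:
            raise ValueError("n_female out of range")
        ids = tuple(f"P{i + 1:02d}" for i in range(n_participants))
        sex = tuple("F" if i < n_female else "M" for i in range(n_participants))
        return cls(participant_ids=ids, sex=sex)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def nonbaseline_days(self) -> tuple[int, ...]:
        return tuple(t for t in self.timepoints if t not in self.baseline_days)

    def sex_of(self, participant: str) -> str:
        return self.sex[self.participant_ids.index(participant)]


@dataclass
class ProteinMatrix:
    """Participant × timepoint × assay measurement cube; NaN marks missing.

    `values[i, t, a]` is the measurement of assay `a` for participant `i` on
    study day `design.timepoints[t]`.  `lod[a]` is the per-assay detection
    limit (NaN when no censoring was applied); values at the LOD were
    left-censored but retained, mirroring platforms that report below-LOD
    reads rather than dropping them.
    """

    design: StudyDesign
    assay_ids: list[str]
    values: np.ndarray
    lod: np.ndarray | None = None

    def __post_init__(self):
        expected = (self.design.n_participants, len(self.design.timepoints), len(self.assay_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        finite_or_nan = np.isnan(self.values) | np.isfinite(self.values)
        if not finite_or_nan.all():
            raise ValueError("values must be finite or NaN (missing)")
        if self.lod is None:
            self.lod = np.full(len(self.assay_ids), np.nan)

    def assay_values(self, assay_id: str) -> np.ndarray:
        """(n_participants, n_timepoints) slice for one assay."""
        return self.values[:, :, self.assay_ids.index(assay_id)]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: participant, sex, day, assay_id, value (NaN kept)."""
        d = self.design
        idx = pd.MultiIndex.from_product(
            [d.participant_ids, d.timepoints, self.assay_ids],
            names=["participant", "day", "assay_id"],
        )
        df = pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()
        sex = dict(zip(d.participant_ids, d.sex))
        df.insert(1, "sex", df["participant"].map(sex))
        return df[["participant", "sex", "day", "assay_id", "value"]]

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_long(cls, df: pd.DataFrame, design: StudyDesign | None = None) -> "ProteinMatrix":
        if design is None:
            participants = sorted(df["participant"].unique())
            sex = df.drop_duplicates("participant").set_index("participant")["sex"]
            design = StudyDesign(
                participant_ids=tuple(participants),
                sex=tuple(sex[p] for p in participants),
                timepoints=tuple(sorted(df["day"].unique())),
            )
        assays = list(pd.unique(df["assay_id"]))  # preserve file order
        pi = {p: i for i, p in enumerate(design.participant_ids)}
        ti = {t: i for i, t in enumerate(design.timepoints)}
        ai = {a: i for i, a in enumerate(assays)}
        values = np.full((len(pi), len(ti), len(ai)), np.nan)
        values[
            df["participant"].map(pi).to_numpy(),
            df["day"].map(ti).to_numpy(),
            df["assay_id"].map(ai).to_numpy(),
        ] = df["value"].to_numpy(float)
        return cls(design=design, assay_ids=list(assays), values=values)

    @classmethod
    def read_tsv(cls, path, design: StudyDesign | None = None) -> "ProteinMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
        return cls.from_long(df, design=design)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study.

    cluster_of_assay: archetype index 1..K for signal assays, 0 for null
    assays, −1 for unstructured "noise" assays (random direction, not drawn
    from any archetype).
    """

    cluster_of_assay: dict[str, int]
    archetype_curves: dict[int, np.ndarray]  # per cluster, value at each timepoint
    amplitude_of_assay: dict[str, float]
    sigma_participant: float
    sigma_resid: float
    sex_effect_assays: dict[str, np.ndarray]  # per-timepoint offset added to females
    n_censored: int = 0

    def to_json(self, path) -> None:
        payload = {
            "cluster_of_assay": self.cluster_of_assay,
            "archetype_curves": {str(k): v.tolist() for k, v in self.archetype_curves.items()},
            "amplitude_of_assay": self.amplitude_of_assay,
            "sigma_participant": self.sigma_participant,
            "sigma_resid": self.sigma_resid,
            "sex_effect_assays": {k: v.tolist() for k, v in self.sex_effect_assays.items()},
            "n_censored": self.n_censored,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Temporal archetypes
# ---------------------------------------------------------------------------

# Nine parametric trajectory templates on the study-day axis, in SD units at
# unit amplitude.  They mimic the qualitative cluster shapes seen in
# week-long-fast proteomes: three rising profiles, five falling profiles with
# staggered onset/recovery, and one transient intracellular-leakage profile
# that returns to baseline before refeeding.  Values at pre-fast days are 0 by
# construction; other days are piecewise-linear in the knots.
_ARCHETYPE_KNOTS: dict[int, list[tuple[float, float]]] = {
    1: [(0, 0), (1, 0.6), (2, 1), (7, 1), (10, 0.35)],          # early rise, sustained
    2: [(0, 0), (1, 0.4), (2, 1), (3, 0.8), (4, 0.35), (5, 0.1), (6, 0), (7, 0), (10, 0)],  # transient peak d2-3
    3: [(0, 0), (4, 0), (5, 0.25), (6, 0.6), (7, 1), (10, 0.85)],  # late rise, persists post-refeed
    4: [(0, 0), (1, -1), (2, -1), (6, -0.95), (7, -0.9), (10, -0.05)],  # early fall, plateau, recovers
    5: [(0, 0), (1, 0), (2, -0.7), (3, -1), (7, -1), (10, -1)],         # fall from day 2, stays low
    6: [(0, 0), (2, 0), (3, -0.5), (4, -1), (6, -1), (7, -0.8), (10, 0.15)],  # fall from day 3, rebounds
    7: [(0, 0), (3, 0), (4, -0.25), (5, -0.65), (6, -1), (7, -1), (10, -0.6)],  # fall from day 4
    8: [(0, 0), (1, 0), (2, -0.25), (3, -0.5), (4, -0.6), (5, -0.55), (6, -0.4), (7, -0.2), (10, 1)],  # rebound overshoot
    9: [(0, 0), (1, -0.3), (2, -0.75), (3, -1), (4, -0.85), (5, -0.5), (6, -0.15), (7, 0), (10, 0)],  # return by day 7
}

ARCHETYPE_NAMES = {
    1: "early-rise-sustained",
    2: "transient-peak-day2-3",
    3: "late-rise",
    4: "early-fall-plateau",
    5: "fall-from-day2",
    6: "fall-from-day3",
    7: "fall-from-day4",
    8: "rebound-overshoot",
    9: "return-by-day7",
}

N_ARCHETYPES = len(_ARCHETYPE_KNOTS)


def archetype_curve(cluster: int, days: Sequence[float]) -> np.ndarray:
    """Unit-amplitude mean trajectory of one archetype at the given days.

    Days at or before day 0 (pre-fast) evaluate to exactly 0.
    """
    knots = _ARCHETYPE_KNOTS[cluster]
    xs = np.array([k[0] for k in knots], float)
    ys = np.array([k[1] for k in knots], float)
    days = np.asarray(days, float)
    out = np.interp(days, xs, ys, left=0.0, right=ys[-1])
    out[days <= 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# Study generator
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration of the simulated proteomics study.

    Defaults mirror the study's structure: 12 participants (5 F / 7 M), nine
    sampling days, nine temporal archetypes with amplitudes of 1–3 SD units,
    participant random-intercept SD 0.5 and residual SD 0.5 (on the
    pre-fast-standardized scale), mild left-censoring at a 5% detection-limit
    quantile, and sex-differential effects for a small minority of proteins.
    """

    n_participants: int = 12
    n_female: int = 5
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_per_cluster: int = 20
    n_null: int = 100
    n_noise: int = 20
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    sigma_participant: float = 0.5
    sigma_resid: float = 0.5
    lod_quantile: float = 0.05
    sex_effect_rate: float = 0.02
    sex_effect_size: float = 1.0
    missing_rate: float = 0.0  # fraction of (participant, assay) series dropped

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if min(self.n_per_cluster, self.n_null, self.n_noise) < 0:
            raise ValueError("assay counts must be non-negative")
        if self.n_per_cluster + self.n_null + self.n_noise == 0:
            raise ValueError("at least one assay required")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be > 0")
        if self.sigma_participant < 0:
            raise ValueError("sigma_participant must be >= 0")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def generate_study(config: SimConfig, seed: int) -> tuple[ProteinMatrix, SimulationTruth]:
    """Simulate a longitudinal proteomics study with known cluster structure.

    value(i, t, a) = amplitude_a · archetype_a(t) + u_i + sex term + ε,
    with u_i ~ N(0, σ_u²) per (participant, assay) and ε ~ N(0, σ_e²).
    Values below the per-assay LOD (a low quantile of that assay's values)
    are left-censored to the LOD but kept in the matrix.
    """
    config.validate()
    rng = child_rng(seed, SEED_STUDY)
    design = StudyDesign.default(config.n_participants, config.n_female)
    if tuple(config.timepoints) != DEFAULT_TIMEPOINTS:
        design = StudyDesign(
            participant_ids=design.participant_ids,
            sex=design.sex,
            timepoints=tuple(config.timepoints),
        )
    days = np.asarray(design.timepoints, float)
    n_p, n_t = design.n_participants, len(days)

    assay_ids: list[str] = []
    cluster_of: dict[str, int] = {}
    for k in range(1, N_ARCHETYPES + 1):
        for j in range(config.n_per_cluster):
            aid = f"SIG{k}_{j + 1:04d}"
            assay_ids.append(aid)
            cluster_of[aid] = k
    for j in range(config.n_null):
        aid = f"NUL_{j + 1:04d}"
        assay_ids.append(aid)
        cluster_of[aid] = 0
    for j in range(config.n_noise):
        aid = f"NOI_{j + 1:04d}"
        assay_ids.append(aid)
        cluster_of[aid] = -1
    n_a = len(assay_ids)

    curves = {k: archetype_curve(k, days) for k in range(1, N_ARCHETYPES + 1)}
    amp_lo, amp_hi = config.amplitude_range
    amplitudes = rng.uniform(amp_lo, amp_hi, size=n_a)

    # Mean trajectory per assay (n_t, n_a)
    mean = np.zeros((n_t, n_a))
    nonbase = np.array([t not in design.baseline_days for t in design.timepoints])
    for a, aid in enumerate(assay_ids):
        k = cluster_of[aid]
        if k > 0:
            mean[:, a] = amplitudes[a] * curves[k]
        elif k == -1:
            # unstructured response: random direction over non-baseline days
            direction = rng.standard_normal(nonbase.sum())
            direction /= np.linalg.norm(direction)
            mean[nonbase, a] = amplitudes[a] * direction
        else:
            amplitudes[a] = 0.0

    # Sex-differential assays: additive offset for females on fasting days.
    sex_assays: dict[str, np.ndarray] = {}
    n_sex = int(round(config.sex_effect_rate * n_a))
    if n_sex > 0 and len(set(design.sex)) == 2:
        chosen = rng.choice(n_a, size=n_sex, replace=False)
        fast_mask = np.array([t in design.fasting_days for t in design.timepoints])
        for a in sorted(chosen):
            offset = np.where(fast_mask, config.sex_effect_size, 0.0)
            sex_assays[assay_ids[a]] = offset

    female = np.array([s == "F" for s in design.sex])
    u = rng.normal(0.0, config.sigma_participant, size=(n_p, n_a))
    eps = rng.normal(0.0, config.sigma_resid, size=(n_p, n_t, n_a))
    values = mean[None, :, :] + u[:, None, :] + eps
    for aid, offset in sex_assays.items():
        a = assay_ids.index(aid)
        values[female, :, a] += offset[None, :]

    # Panel-style missingness: whole (participant, assay) series dropped.
    if config.missing_rate > 0:
        drop = rng.random((n_p, n_a)) < config.missing_rate
        values[drop[:, None, :].repeat(n_t, axis=1)] = np.nan

    # Left-censoring at the per-assay LOD.
    lod = np.full(n_a, np.nan)
    n_censored = 0
    if config.lod_quantile > 0:
        flat = values.reshape(-1, n_a)
        lod = np.nanquantile(flat, config.lod_quantile, axis=0)
        below = flat < lod[None, :]
        n_censored = int(np.nansum(below))
        values = np.where(np.isnan(values), np.nan, np.maximum(values, lod[None, None, :]))

    matrix = ProteinMatrix(design=design, assay_ids=assay_ids, values=values, lod=lod)
    truth = SimulationTruth(
        cluster_of_assay=cluster_of,
        archetype_curves=curves,
        amplitude_of_assay=dict(zip(assay_ids, amplitudes.tolist())),
        sigma_participant=config.sigma_participant,
        sigma_resid=config.sigma_resid,
        sex_effect_assays=sex_assays,
        n_censored=n_censored,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Exposure tracks
# ---------------------------------------------------------------------------


@dataclass
class ExposureConfig:
    """Weight and ketone (3-hydroxybutyrate) track parameters.

    Defaults reproduce the study's published physiology: ~77.5 kg (SD 15.7)
    baseline weight, an average 5.7 kg loss over the 7 fasting days with a
    partial rebound to −3.1 kg by day 10, and a ketone rise saturating near
    5.5 mmol/L with refeed clearance.
    """

    weight_baseline_mean: float = 77.5
    weight_baseline_sd: float = 15.7
    weight_loss_total: float = 5.7
    weight_loss_sd: float = 2.0  # between-participant SD of the total loss
    weight_rebound: float = 3.1  # mean deficit remaining at refeed day
    weight_noise_sd: float = 0.1  # scale accuracy
    bhb_baseline: float = 0.1
    bhb_max: float = 5.5
    bhb_rate: float = 0.35  # 1/day saturation rate
    bhb_sd: float = 0.6  # between-participant SD of the plateau
    bhb_noise_sd: float = 0.05


def generate_exposures(
    design: StudyDesign, config: ExposureConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per (participant, day) weight and 3-hydroxybutyrate tracks.

    The mean weight trajectory is monotone non-increasing during fasting with
    a partial rebound after refeeding; the mean ketone trajectory starts at
    the baseline level and rises monotonically during fasting.
    """
    if config is None:
        config = ExposureConfig()
    if not design.fasting_days:
        raise ValueError("design has no fasting days")
    rng = child_rng(seed, SEED_EXPOSURES)
    last_fast = max(design.fasting_days)
    rows = []
    n = design.n_participants
    w0 = rng.normal(config.weight_baseline_mean, config.weight_baseline_sd, size=n)
    loss = rng.normal(config.weight_loss_total, config.weight_loss_sd, size=n)
    loss = np.maximum(loss, 0.0)
    plateau = np.maximum(rng.normal(config.bhb_max, config.bhb_sd, size=n), 0.0)
    for i, pid in enumerate(design.participant_ids):
        for day in design.timepoints:
            if day <= 0:
                w_mu = w0[i]
                b_mu = config.bhb_baseline
            elif day <= last_fast:
                frac = day / last_fast
                w_mu = w0[i] - loss[i] * frac
                b_mu = config.bhb_baseline + (plateau[i] - config.bhb_baseline) * (
                    1.0 - np.exp(-config.bhb_rate * day)
                )
            else:  # refeed
                rebound_frac = config.weight_rebound / max(config.weight_loss_total, 1e-12)
                w_mu = w0[i] - loss[i] * rebound_frac
                b_mu = config.bhb_baseline
            w = w_mu + rng.normal(0.0, config.weight_noise_sd)
            b = max(b_mu + rng.normal(0.0, config.bhb_noise_sd), 0.0)
            rows.append((pid, day, w, b))
    return pd.DataFrame(rows, columns=["participant", "day", "weight", "bhb"])


# ---------------------------------------------------------------------------
# GWAS regions
# ---------------------------------------------------------------------------


@dataclass
class GwasRegion:
    """One cis region with summary statistics for two traits and an LD matrix.

    Simulated under the summary-statistics model z ~ N(Rλ, R), where λ is
    nonzero only at the scenario's causal variants (H0: none; H1: protein
    only; H2: outcome only; H3: distinct variants; H4: the same variant).
    """

    variant_ids: list[str]
    chrom: str
    positions: np.ndarray  # 1-based bp
    effect_allele: list[str]
    other_allele: list[str]
    stats: dict[str, pd.DataFrame]  # trait name -> beta, se, n, eaf, z
    ld: np.ndarray
    scenario: str
    causal_variants: dict[str, list[int]]  # trait -> variant indices

    def sumstats(self, trait: str) -> pd.DataFrame:
        df = self.stats[trait].copy()
        df.insert(0, "variant_id", self.variant_ids)
        df.insert(1, "chr", self.chrom)
        df.insert(2, "pos", self.positions)
        df.insert(3, "effect_allele", self.effect_allele)
        df.insert(4, "other_allele", self.other_allele)
        return df

    def write(self, prefix) -> None:
        """TSV per trait, LD as a whitespace square matrix + variant sidecar."""
        for trait in self.stats:
            self.sumstats(trait).to_csv(f"{prefix}.{trait}.tsv", sep="\t", index=False)
        np.savetxt(f"{prefix}.ld", self.ld, fmt="%.8g")
        with open(f"{prefix}.ld.vars", "w") as fh:
            fh.write("\n".join(self.variant_ids) + "\n")


def make_ld_matrix(
    m: int, model: str = "block", rho: float = 0.9, n_blocks: int = 5
) -> np.ndarray:
    """LD correlation matrix: AR(1) within blocks (or one global AR(1))."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if model not in ("block", "ar1"):
        raise ValueError("ld model must be 'block' or 'ar1'")
    if model == "ar1":
        n_blocks = 1
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    R = np.zeros((m, m))
    for b in range(n_blocks):
        lo, hi = bounds[b], bounds[b + 1]
        idx = np.arange(lo, hi)
        if len(idx) == 0:
            continue
        lag = np.abs(idx[:, None] - idx[None, :])
        R[lo:hi, lo:hi] = rho ** lag
    np.fill_diagonal(R, 1.0)
    return R


_UNAMBIGUOUS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


def generate_gwas_region(
    scenario: str,
    m_variants: int = 100,
    n1: int = 10000,
    n2: int = 50000,
    effect_sizes: float | tuple[float, float] = 8.0,
    ld_model: str = "block",
    rho: float = 0.9,
    n_blocks: int = 5,
    seed: int = 0,
    chrom: str = "1",
    start: int = 1_000_000,
    trait_names: tuple[str, str] = ("protein", "outcome"),
) -> GwasRegion:
    """Simulate one two-trait region under a colocalization scenario H0–H4.

    `effect_sizes` is the non-centrality λ at the causal variant(s) (scalar or
    per-trait pair); the marginal z-vector of each trait is drawn from
    N(Rλ, R) and converted to betas via se = 1/sqrt(n·2·eaf·(1−eaf)).
    """
    scenario = scenario.upper()
    if scenario not in ("H0", "H1", "H2", "H3", "H4"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if m_variants < 1:
        raise ValueError("m_variants must be >= 1")
    if scenario == "H3" and m_variants < 2:
        raise ValueError("H3 requires at least 2 variants")
    rng = child_rng(seed, SEED_GWAS)
    lam1, lam2 = (
        effect_sizes if isinstance(effect_sizes, (tuple, list)) else (effect_sizes, effect_sizes)
    )
    R = make_ld_matrix(m_variants, model=ld_model, rho=rho, n_blocks=n_blocks)
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(m_variants))

    # Causal placement. H3 puts the two causals in different LD blocks when
    # the panel has more than one block, so the signals are truly distinct.
    block_id = (np.arange(m_variants) * (n_blocks if ld_model == "block" else 1)) // m_variants
    causal: dict[str, list[int]] = {trait_names[0]: [], trait_names[1]: []}
    if scenario in ("H1", "H4"):
        j = int(rng.integers(m_variants))
        causal[trait_names[0]] = [j]
        if scenario == "H4":
            causal[trait_names[1]] = [j]
    elif scenario == "H2":
        causal[trait_names[1]] = [int(rng.integers(m_variants))]
    elif scenario == "H3":
        j1 = int(rng.integers(m_variants))
        other = np.nonzero(block_id != block_id[j1])[0]
        pool = other if len(other) else np.delete(np.arange(m_variants), j1)
        j2 = int(rng.choice(pool))
        causal[trait_names[0]] = [j1]
        causal[trait_names[1]] = [j2]

    eaf = rng.uniform(0.05, 0.95, size=m_variants)
    positions = np.sort(rng.choice(np.arange(1, 10 * m_variants + 1), size=m_variants, replace=False)) * 100 + start
    alleles = [_UNAMBIGUOUS[int(k)] for k in rng.integers(len(_UNAMBIGUOUS), size=m_variants)]
    variant_ids = [f"rs{chrom}_{p}" for p in positions]

    stats = {}
    for trait, lam, n in zip(trait_names, (lam1, lam2), (n1, n2)):
        lam_vec = np.zeros(m_variants)
        for j in causal[trait]:
            lam_vec[j] = lam
        z = R @ lam_vec + chol @ rng.standard_normal(m_variants)
        se = 1.0 / np.sqrt(n * 2.0 * eaf * (1.0 - eaf))
        stats[trait] = pd.DataFrame(
            {"beta": z * se, "se": se, "n": n, "eaf": eaf, "z": z}
        )
    return GwasRegion(
        variant_ids=variant_ids,
        chrom=chrom,
        positions=positions.astype(int),
        effect_allele=[a[0] for a in alleles],
        other_allele=[a[1] for a in alleles],
        stats=stats,
        ld=R,
        scenario=scenario,
        causal_variants=causal,
    )


# ---------------------------------------------------------------------------
# Gene sets and annotation fixtures
# ---------------------------------------------------------------------------


def generate_genesets(
    n_sets: int,
    size_range: tuple[int, int] = (10, 50),
    n_genes: int = 500,
    seed: int = 0,
    prefix: str = "SET",
) -> dict[str, list[str]]:
    """Random gene-set collection over the universe GENE0001..GENE{n_genes}."""
    if n_genes < 1:
        raise ValueError("empty gene universe")
    if size_range[0] < 1 or size_range[1] < size_range[0]:
        raise ValueError("invalid size_range")
    rng = child_rng(seed, SEED_GENESETS)
    universe = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(size_range[0], min(size_range[1], n_genes) + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"{prefix}{s + 1:03d}"] = [universe[g] for g in sorted(members)]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            genes = "\t".join(sets[set_id])
            fh.write(f"{set_id}\t{description}\t{genes}\n")


SPECIFICITY_CLASSES = ("enhanced", "enriched", "group enriched")


def generate_tissue_annotation(
    genes: Sequence[str],
    tissues: Sequence[str] = ("liver", "pancreas", "adipose", "intestine", "brain", "muscle"),
    specificity_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue-specificity table: gene, unit, class (HPA-style vocabulary).

    Each gene is tissue-specific with probability `specificity_rate`; specific
    genes get one or occasionally two tissues with a class drawn from
    {enhanced, enriched, group enriched}.  Non-specific genes get class "none".
    """
    if not 0 <= specificity_rate <= 1:
        raise ValueError("specificity_rate must be in [0, 1]")
    rng = child_rng(seed, SEED_ANNOTATION)
    rows = []
    for g in genes:
        if rng.random() < specificity_rate:
            k = 2 if rng.random() < 0.1 else 1
            units = rng.choice(len(tissues), size=min(k, len(tissues)), replace=False)
            for u in units:
                cls = SPECIFICITY_CLASSES[int(rng.integers(len(SPECIFICITY_CLASSES)))]
                rows.append((g, tissues[int(u)], cls))
        else:
            rows.append((g, "", "none"))
    return pd.DataFrame(rows, columns=["gene", "unit", "class"])
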