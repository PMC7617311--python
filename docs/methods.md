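# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the limitations of the package.

## Measurement model and standardization

Protein measurements are treated as relative log2-scale abundances (NPX-like
units). Before modelling, every assay is scaled by the mean and standard
deviation of its pre-fast values pooled across participants, so all effects
read as pre-fast SD units. The pooling is across participants because a
single pre-fast sample per participant makes a within-participant SD
undefined. Assays with fewer than two pre-fast values or zero pre-fast
variance are excluded with a logged reason rather than propagated as NaN.
Values below an assay's detection limit are retained (left-censored to the
LOD in the generator), mirroring platforms that report below-LOD reads.

## Per-protein trajectory model

For one protein with measurements `y_it` (participant i, study day t):

    y_it = β_0 + Σ_{t ∉ baseline} β_t·1[day = t] + u_i + ε_it,
    u_i ~ N(0, σ_u²), ε_it ~ N(0, σ_e²)

fitted by REML. The implementation profiles the likelihood over the variance
ratio θ = σ_u²/σ_e²: given θ, GLS estimates and the profiled criterion are
closed-form via per-participant block inversion of I + θ·ZZᵀ, so each fit is
a one-dimensional bounded optimization (Brent, absolute tolerance 1e−10,
θ ∈ [0, 1e5] with an explicit boundary check so σ̂_u² = 0 is attainable).
This matches generic mixed-model software to ~1e−6 (cross-checked against
statsmodels MixedLM in the tests) while being fast enough to fit thousands
of assays in seconds. Unbalanced data (missing participant×panel series) are
handled by the same machinery without imputation.

**Global "any change" test.** The default is a Wald F on the timepoint
contrast block — using the full REML covariance of the contrasts, which are
correlated through the shared baseline — with containment denominator
degrees of freedom n − rank(X) − (N−1). For a complete balanced design this
statistic is numerically identical to the exact repeated-measures ANOVA F,
and simulation shows it is uniform under the null at the study's size
(12 participants × 9 days). The asymptotic likelihood-ratio χ²(T−1) on ML
fits is available behind `global_test="lrt"`; it was measured
anti-conservative at this sample size (type-I ≈ 0.07 at nominal 0.05), which
is why it is not the default. Per-timepoint p-values use a t reference on
the containment df for the same reason. Satterthwaite/Kenward–Roger
corrections are deliberately out of scope.

**Sex interaction.** A likelihood-ratio test (ML) of
timepoint + sex + timepoint:sex against the additive model, χ² with T−1 df;
requires at least two participants of each sex.

**Exposure associations.** `y_it = α + γ·x_it + a_i + b_t + ε` with crossed
random intercepts for participant and day, fitted by a two-parameter profile
REML; the Woodbury identity reduces every evaluation to (N+T)×(N+T) algebra.
The Wald test of γ is calibrated when the outcome follows the
participant-intercept null; with strong day-level random variation in the
outcome and only ~9 day levels, any Wald test at this size is optimistic —
a known small-sample limitation.

**FDR.** Benjamini–Hochberg step-up, one family per analysis (global tests
across assays; each exposure across assays; interaction tests across
assays).

## Directional clustering

Significant proteins (global q < 0.05) are summarized by z_t = β_t/SE_t over
the 8 non-baseline days and normalized to the unit sphere S⁷, so proteins
cluster by temporal *shape* irrespective of amplitude. The model is a
mixture of von Mises–Fisher components plus a fixed uniform noise component
with estimated weight π_0:

    p(x) = π_0·Γ(d/2)/(2π^{d/2}) + Σ_k π_k·C_d(κ_k)·exp(κ_k μ_kᵀx)

fitted by EM. Numerics: log C_d(κ) uses exponentially scaled Bessel
functions (`ive`) for stability; the M-step concentration uses the Banerjee
closed form with optional Newton refinement of A_d(κ) = r̄; r̄ is capped at
1 − 1e−8 and κ at 1e4 so point-mass clusters cannot overflow. Empty
components are re-seeded once at the worst-explained point, then dropped
with a warning. Initialization is spherical k-means++ with 10 restarts from
fixed child seeds (EM on spheres is multimodal); the K-scan additionally
tries a warm start that grows the best (K−1)-solution by one component, so
the BIC curve reflects well-optimized fits rather than restart noise.

The cluster count is the first BIC plateau: the smallest K with
(BIC_K − BIC_{K+1})/|BIC_K| < 0.005, scanning K = 1..20, with
BIC = −2·loglik + p·log n and p = K(d−1) + K + K. The selected K is refitted
with the full restart budget before hard assignment
(argmax responsibility, ties to the lowest component index; the noise
component is last).

## Enrichment

Over-representation uses the one-sided hypergeometric tail on the 2×2 table
with the platform's protein-coding genes as background (sets are first
intersected with the background); BH within each collection. Redundancy
pruning, used for figure-ready output, iterates: retain the candidate
covering the most significant query genes (ties → smaller p, then
lexicographic id), delete every candidate sharing at least half of *its own*
members with the retained set, repeat. "Coverage" as query-gene count and
the candidate-relative overlap denominator are the default readings; the
set-size alternative is exposed as a flag. Tissue/cell-type specificity
("enhanced", "enriched", "group enriched" classes) is tested per unit with
a two-sided Fisher exact test of significant × specific counts. Assays
targeting protein complexes are split into component genes before gene-level
analysis; where several assays cover one gene, the lowest-q record is kept.

## Fine-mapping and colocalization

Cis regions are the protein-coding gene ± 500 kb with the extended MHC
(chr6:25.5–34.0 Mb) excluded; coordinates are 1-based inclusive throughout.
Fine-mapping fits the sum-of-single-effects model on z-scores,
z ~ N(Rb, R): each effect is refit on the residual z obtained by removing
the other effects' expected contributions through R, with per-variant Bayes
factors under a N(0, σ0²) prior (σ0² optimized per effect by maximizing the
single-effect Bayes factor, collapsing to 0 for null effects). Convergence
is by relative ELBO change < 1e−6; the ELBO is monotone by construction and
asserted in tests. R must be PSD within 1e−8 (regularize as R + 1e−8·I
otherwise). 95% credible sets are minimal α-prefixes per active effect,
purity = min |r| among members (singletons 1.0), filtered at purity ≥ 0.5
and deduplicated. Because summary-statistic fits can produce correlated
credible sets, L is scanned over 2..10 and the fit maximizing the number of
credible-set leads with pairwise r² < 0.25 (exact maximum-subset search) is
carried forward, ties to the smallest L.

Colocalization uses Wakefield log-ABFs,
lABF = ½log(V/(V+W)) + z²W/(2(V+W)), with prior effect variances
W = 0.15² (quantitative) and 0.2² (binary) — the framework's conventional
values, configurable — and priors p1 = p2 = 1e−4, p12 = 5e−6. The five
hypothesis sums are accumulated by log-sum-exp; PP3 is computed via a stable
log-difference and is exactly 0 for single-variant panels. The
fine-mapping-before-colocalization route runs the same enumeration on every
credible-set pair using each effect's per-variant Bayes factors. A
protein–trait link is accepted iff PP(H4) ≥ 0.80 and the shared lead variant
is a credible-set lead cis-pQTL or a proxy with r² > 0.8. Accepted links
form a bipartite graph; an edge is "concordant" when the protein-increasing
allele also increases the trait, after aligning both traits to one effect
allele (strand-ambiguous A/T and C/G variants are dropped with a logged
count), so the sign is invariant to allele relabeling. An optional
suggestive pre-filter on trait regions (max |z| > 4.89, i.e. p < 1e−6) is
off by default for simulations.

Liability-scale rescaling of case/control effect estimates is out of scope.

## Synthetic-data generator

The generator emulates the study that the analysis chain targets; defaults
are the study conditions, chosen once:

- **Design**: 12 participants (5 F / 7 M), days −2, 1..7, 10; baseline
  day −2.
- **Archetypes**: nine piecewise-linear trajectory templates (early rise
  sustained; transient peak day 2–3; late rise; early fall plateau; falls
  starting day 2/3/4 with distinct refeed behaviour; rebound overshoot;
  return by day 7). Shapes are a design choice mimicking the qualitative
  cluster profiles of week-long fasts; knots were placed so that no two
  templates exceed cosine 0.85 over the non-baseline days, i.e. all nine are
  directionally resolvable. Amplitudes default to Uniform(1, 3) SD units.
- **Noise**: participant random intercept σ_u = 0.5 and residual σ_e = 0.5
  on the standardized scale — between-participant spread about half the
  total, consistent with a homogeneous volunteer panel.
- **Censoring**: per-assay LOD at the 5% quantile by default; censored
  values are clamped to the LOD but retained.
- **Sex effects**: 2% of assays get a +1 SD offset for females on fasting
  days.
- **Exposures**: baseline weight N(77.5, 15.7²) kg, mean loss 5.7 kg over 7
  days with partial rebound to −3.1 kg at day 10; 3-hydroxybutyrate rising
  from ~0.1 mmol/L along a saturating curve toward ~5.5 mmol/L and clearing
  after refeed.
- **GWAS regions**: M = 100 variants, LD = 5 blocks of AR(1) with ρ = 0.9
  (block structure gives controllable credible-set purity); marginal
  z ~ N(Rλ, R) per trait with λ placed per scenario H0–H4 (H3 causals in
  different blocks); betas via se = 1/√(n·2·eaf·(1−eaf)). The pipeline's
  planted cis-pQTLs use λ = 10, matching the magnitude of sentinel plasma
  pQTL associations; focused calibration checks use λ = 6–8.
- **Seeding**: one global integer seed; each generator draws from a child
  stream identified by a fixed offset, so components are independently
  reproducible and identical seeds give bit-identical output.

What the generator does *not* emulate: assay-specific noise heterogeneity,
plate/batch structure, correlated proteins (co-regulation), heavy-tailed
measurement error, realistic minor-allele-frequency spectra or genotyped LD,
and selection effects in which proteins are assayed. Passing tests therefore
demonstrate correctness and calibration of the *methods* under the stated
generative model, not performance guarantees on any real proteome.

## Pipeline

Stages communicate through plain-text artifacts (TSV with a `# run:<tag>`
header line, GMT, JSON, GraphML) in a run directory, so each stage can be
re-run from cached inputs with identical downstream results. The manifest
records the seed, a hash of the analysis configuration (stage selection
excluded), per-stage row counts, and the number of logged warnings; no
timestamps are written, so identical configuration + seed reproduces every
output byte-for-byte. The default simulated study uses 300 assays
(9 × 20 signal, 100 null, 20 noise) and 10 planted GWAS regions (5 shared-
signal, 5 decoys alternating no-signal and distinct-signal scenarios) —
sizes chosen so a complete run takes well under a minute while every stage
operates at non-trivial scale.

## Known limitations

- The global F test is exact only for complete balanced designs; under
  missingness the containment df is an approximation (slightly conservative
  in simulation).
- Wald tests for exposures with strong day-level structure in the outcome
  are optimistic at N = 12 (documented above).
- The BIC plateau rule depends on well-optimized fits at every K; the
  restart budget trades runtime against scan stability.
- Because every per-day contrast shares the single pre-fast baseline mean,
  the noise on the scaled effect vectors is strongly positively correlated
  across days (one dominant variance axis). Direction clusters are therefore
  anisotropic, and at large per-cluster counts (≈100 proteins per profile)
  the isotropic vMF mixture earns genuine likelihood by splitting a profile
  into a tight core and diffuse shell, so the BIC plateau can settle at
  10–12 rather than the 9 planted profiles even while assignment accuracy
  stays high (ARI ≥ 0.89 in our simulations). On isotropic vMF data with the
  same layout the plateau recovers the true count exactly; at the
  20–30-per-cluster scale of the default pipeline the penalty term dominates
  and the planted count is recovered.
- The z-scale sum-of-single-effects model assumes the LD panel matches the
  summary statistics; LD mismatch is not modelled.
- Enrichment treats gene sets as flat memberships (no topology), and the
  specificity test conditions on the annotation as given.
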