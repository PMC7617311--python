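"""End-to-end pipeline: simulate → standardize → fit → cluster → enrich →
fine-map/colocalize → network.

Every stage reads and writes plain-text artifacts (TSV, GMT, JSON, GraphML)
in a run directory, so stages can be re-run individually from cached inputs;
a JSON manifest records the seed, a hash of the configuration, per-stage row
counts and warning counts.  Given identical configuration and seed the run
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as sd
from . import trajectory_stats as ts
from . import directional_clustering as dc
from . import set_enrichment as se
from . import finemap_coloc as fc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GwasSimConfig", "run_all", "load_config"]


@dataclass
class GwasSimConfig:
    """Planted protein–trait regions for the genetics stages.

    Strong cis-pQTL leads are simulated at a non-centrality of z ≈ 10,
    matching the magnitude of sentinel cis-pQTL associations reported for
    plasma proteins.
    """

    n_h4: int = 5
    n_decoy: int = 5
    decoy_scenarios: tuple[str, ...] = ("H0", "H3")
    m_variants: int = 100
    effect_size: float = 10.0
    n_protein_gwas: int = 10000
    n_trait_gwas: int = 50000
    ld_model: str = "block"
    rho: float = 0.9
    n_blocks: int = 5


@dataclass
class RunConfig:
    """Pipeline configuration (YAML round-trippable)."""

    seed: int = 1
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    exposures: sd.ExposureConfig = field(default_factory=sd.ExposureConfig)
    gwas: GwasSimConfig = field(default_factory=GwasSimConfig)
    q_cutoff: float = 0.05
    per_test_p: float = 4.7e-5  # per-test significance constant (reporting only)
    k_max: int = 20
    plateau_tol: float = 0.005
    n_genesets: int = 20
    pp4_cutoff: float = 0.80
    r2_independent: float = 0.25
    r2_proxy: float = 0.8
    coverage: float = 0.95
    min_purity: float = 0.5
    L_min: int = 2
    L_max: int = 10
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-6
    trait_screen: bool = False  # suggestive pre-filter (min |z| > 4.89) on trait regions
    stages: tuple[str, ...] = (
        "simulate", "fit", "cluster", "enrich", "tissue-enrich", "exposures",
        "finemap", "coloc", "network",
    )

    def validate(self) -> None:
        self.sim.validate()
        for name, val, lo, hi in [
            ("q_cutoff", self.q_cutoff, 0, 1), ("pp4_cutoff", self.pp4_cutoff, 0, 1),
            ("r2_independent", self.r2_independent, 0, 1), ("r2_proxy", self.r2_proxy, 0, 1),
            ("coverage", self.coverage, 0, 1), ("min_purity", self.min_purity, 0, 1),
            ("p12", self.p12, 0, 1),
        ]:
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if not 1 <= self.L_min <= self.L_max:
            raise ValueError("need 1 <= L_min <= L_max")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = sd.SimConfig(**{**d["sim"], "timepoints": tuple(d["sim"].get("timepoints", sd.DEFAULT_TIMEPOINTS)), "amplitude_range": tuple(d["sim"].get("amplitude_range", (1.0, 3.0)))})
        if "exposures" in d:
            d["exposures"] = sd.ExposureConfig(**d["exposures"])
        if "gwas" in d:
            g = dict(d["gwas"])
            g["decoy_scenarios"] = tuple(g.get("decoy_scenarios", ("H0", "H3")))
            d["gwas"] = GwasSimConfig(**g)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (stage selection excluded, so a
        partial rerun over cached inputs carries the same run tag)."""
        d = asdict(self)
        d.pop("stages", None)
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def _write_tsv(df: pd.DataFrame, path: Path, run_tag: str) -> int:
    """TSV with the run hash as a leading comment line; returns the row count."""
    with open(path, "w") as fh:
        fh.write(f"# run:{run_tag}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    return len(df)


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _gene_of(assay_id: str) -> str:
    return f"G_{assay_id}"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    matrix, truth = sd.generate_study(config.sim, config.seed)
    df = matrix.to_long()
    counts["study_rows"] = _write_tsv(df, outdir / "study.tsv", tag)
    truth.to_json(outdir / "truth.json")
    expo = sd.generate_exposures(matrix.design, config.exposures, config.seed)
    counts["exposure_rows"] = _write_tsv(expo, outdir / "exposures.tsv", tag)

    # Gene universe: one gene per assay (the platform background).  Gene-set
    # fixtures: one planted set per archetype cluster (a sample of the
    # cluster's genes diluted with random universe genes) plus random sets.
    rng = sd.child_rng(config.seed, sd.SEED_GENESETS)
    universe = [_gene_of(a) for a in matrix.assay_ids]
    by_cluster: dict[int, list[str]] = {}
    for aid, k in truth.cluster_of_assay.items():
        by_cluster.setdefault(k, []).append(_gene_of(aid))
    sets: dict[str, frozenset] = {}
    for k in sorted(by_cluster):
        if k <= 0 or len(by_cluster[k]) < 4:
            continue
        members = list(by_cluster[k])
        take = rng.choice(len(members), size=max(3, int(0.6 * len(members))), replace=False)
        chosen = {members[i] for i in take}
        extra = rng.choice(len(universe), size=5, replace=False)
        chosen |= {universe[i] for i in extra}
        sets[f"CLUSTER_PATHWAY_{k}"] = frozenset(chosen)
    for s in range(config.n_genesets):
        size = int(rng.integers(10, 40))
        idx = rng.choice(len(universe), size=size, replace=False)
        sets[f"RANDOM_{s + 1:03d}"] = frozenset(universe[i] for i in idx)
    coll = se.GeneSetCollection(name="synthetic", sets=sets, source="KEGG-like")
    se.write_gmt(coll, outdir / "genesets.gmt")
    counts["gene_sets"] = len(coll)
    ann = sd.generate_tissue_annotation(universe, seed=config.seed)
    counts["annotation_rows"] = _write_tsv(ann, outdir / "annotation.tsv", tag)


def stage_fit(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    matrix = sd.ProteinMatrix.read_tsv(outdir / "study.tsv")
    std, excluded = ts.standardize(matrix)
    counts["assays_excluded_standardize"] = len(excluded)
    _, table = ts.fit_all_trajectories(std)
    counts["trajectory_rows"] = _write_tsv(table, outdir / "trajectories.tsv", tag)
    glob = table[table["term"] == "global"]
    counts["n_significant"] = int((glob["q"] < config.q_cutoff).sum())


def stage_exposures(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    matrix = sd.ProteinMatrix.read_tsv(outdir / "study.tsv")
    std, _ = ts.standardize(matrix)
    expo = _read_tsv(outdir / "exposures.tsv")
    frames = []
    for name in ("weight", "bhb"):
        frames.append(ts.associate_exposure_all(std, expo, name))
    out = pd.concat(frames, ignore_index=True)
    counts["exposure_assoc_rows"] = _write_tsv(out, outdir / "exposure_associations.tsv", tag)


def stage_cluster(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    table = _read_tsv(outdir / "trajectories.tsv")
    try:
        dm = dc.build_direction_matrix(table, q_threshold=config.q_cutoff)
    except ValueError:
        logger.warning("cluster stage: no significant assays; writing empty output")
        _write_tsv(pd.DataFrame(columns=["assay_id", "cluster", "max_responsibility"]),
                   outdir / "clusters.tsv", tag)
        counts["n_clustered"] = 0
        return
    k_star, models = dc.select_k(dm, k_max=config.k_max, plateau_tol=config.plateau_tol,
                                 seed=config.seed)
    model = models[k_star]
    labels = dc.assign_hard(model, dm)
    logw = model.log_component_matrix(dm.X)
    maxresp = np.exp(logw - np.logaddexp.reduce(logw, axis=1, keepdims=True)).max(axis=1)
    out = pd.DataFrame({
        "assay_id": dm.assay_ids,
        "cluster": [labels[a] for a in dm.assay_ids],
        "max_responsibility": maxresp,
    })
    counts["n_clustered"] = _write_tsv(out, outdir / "clusters.tsv", tag)
    counts["k_selected"] = k_star
    dump = model.to_dict()
    dump["bic_curve"] = {str(k): m.bic for k, m in sorted(models.items())}
    with open(outdir / "cluster_model.json", "w") as fh:
        json.dump(dump, fh, indent=1, sort_keys=True)


def stage_enrich(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    table = _read_tsv(outdir / "trajectories.tsv")
    glob = table[table["term"] == "global"]
    id_map = {a: [_gene_of(a)] for a in glob["assay_id"]}
    gene_level = se.map_assays(glob, id_map)
    coll = se.read_gmt(outdir / "genesets.gmt", source="KEGG-like")
    background = set(gene_level["gene"])
    query = set(gene_level.loc[gene_level["q"] < config.q_cutoff, "gene"])
    if not query:
        logger.warning("enrich stage: empty query; writing empty output")
        _write_tsv(pd.DataFrame(), outdir / "enrichment.tsv", tag)
        counts["enrichment_rows"] = 0
        return
    results = se.overrepresentation(query, background, coll)
    significant = [r for r in results if r.q < config.q_cutoff]
    se.prune_redundant(significant)
    rows = [{
        "set_id": r.set_id, "overlap": r.overlap, "query_size": r.query_size,
        "set_size": r.set_size, "background_size": r.background_size,
        "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
        "retained": r.retained if r.q < config.q_cutoff else False,
    } for r in results]
    counts["enrichment_rows"] = _write_tsv(pd.DataFrame(rows), outdir / "enrichment.tsv", tag)


def stage_tissue_enrich(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    table = _read_tsv(outdir / "trajectories.tsv")
    glob = table[table["term"] == "global"]
    id_map = {a: [_gene_of(a)] for a in glob["assay_id"]}
    gene_level = se.map_assays(glob, id_map)
    ann = _read_tsv(outdir / "annotation.tsv")
    ann["unit"] = ann["unit"].fillna("")
    sig = dict(zip(gene_level["gene"], gene_level["q"] < config.q_cutoff))
    res = se.specificity_enrichment(sig, ann, unit_type="tissue")
    counts["tissue_rows"] = _write_tsv(res, outdir / "tissue_enrichment.tsv", tag)


def _planted_regions(config: RunConfig, significant: list[str]):
    """Deterministic assignment of planted H4/decoy regions to proteins."""
    scenarios = ["H4"] * config.gwas.n_h4
    for i in range(config.gwas.n_decoy):
        scenarios.append(config.gwas.decoy_scenarios[i % len(config.gwas.decoy_scenarios)])
    regions = []
    for i, scen in enumerate(scenarios):
        if i >= len(significant):
            break
        regions.append({
            "region_id": f"R{i + 1:02d}",
            "protein_assay": significant[i],
            "trait": f"TRAIT{i + 1:02d}",
            "scenario": scen,
        })
    return regions


def stage_finemap_coloc(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    table = _read_tsv(outdir / "trajectories.tsv")
    glob = table[table["term"] == "global"].sort_values(["q", "assay_id"], kind="mergesort")
    significant = list(glob.loc[glob["q"] < config.q_cutoff, "assay_id"])
    regions = _planted_regions(config, significant)
    g = config.gwas
    cs_rows, coloc_rows, links = [], [], []
    plan_rows = []
    for i, reg in enumerate(regions):
        region = sd.generate_gwas_region(
            reg["scenario"], m_variants=g.m_variants, n1=g.n_protein_gwas,
            n2=g.n_trait_gwas, effect_sizes=g.effect_size, ld_model=g.ld_model,
            rho=g.rho, n_blocks=g.n_blocks, seed=config.seed * 1000 + i,
            chrom=str((i % 5) + 1), start=1_000_000 + 2_000_000 * i,
        )
        region.write(outdir / f"region_{reg['region_id']}")
        plan_rows.append({**reg, "m_variants": g.m_variants})
        z_p = region.stats["protein"]["z"].to_numpy()
        z_t = region.stats["outcome"]["z"].to_numpy()
        R = region.ld
        if config.trait_screen and np.max(np.abs(z_t)) <= 4.89:
            continue
        fits_p = {L: fc.susie_rss(z_p, R, L=L) for L in range(config.L_min, config.L_max + 1)}
        fit_p, sets_p = fc.select_L(fits_p, R, r2_max=config.r2_independent,
                                    coverage=config.coverage, min_purity=config.min_purity)
        for cs in sets_p:
            cs_rows.append({
                "region_id": reg["region_id"], "protein_assay": reg["protein_assay"],
                "effect": cs.effect, "lead": region.variant_ids[cs.lead],
                "size": len(cs.members), "coverage": cs.coverage, "purity": cs.purity,
            })
        if not sets_p:
            continue
        fit_t = fc.susie_rss(z_t, R, L=config.L_max)
        pairs = fc.coloc_credible_pairs(
            fit_p, fit_t, R, sets1=sets_p, p1=config.p1, p2=config.p2, p12=config.p12,
            variant_ids=region.variant_ids, coverage=config.coverage,
            min_purity=config.min_purity,
        )
        for res in pairs:
            coloc_rows.append({
                "region_id": reg["region_id"], "protein_assay": reg["protein_assay"],
                "trait": reg["trait"], "pair": str(res.cs_pair),
                **{f"pp{h}": res.pp[h] for h in range(5)},
                "lead": res.lead_variant,
            })
        if pairs:
            best = max(pairs, key=lambda r: r.pp4)
            if fc.accept_link(best, sets_p, R, pp4_min=config.pp4_cutoff,
                              r2_proxy=config.r2_proxy):
                j = best.lead
                links.append(fc.ProteinTraitEdge(
                    protein=_gene_of(reg["protein_assay"]), trait=reg["trait"],
                    pp4=best.pp4, variant=region.variant_ids[j],
                    beta_protein=float(region.stats["protein"]["beta"][j]),
                    beta_trait=float(region.stats["outcome"]["beta"][j]),
                ))
    _write_tsv(pd.DataFrame(plan_rows), outdir / "region_plan.tsv", tag)
    counts["credible_set_rows"] = _write_tsv(pd.DataFrame(cs_rows), outdir / "credible_sets.tsv", tag)
    counts["coloc_rows"] = _write_tsv(pd.DataFrame(coloc_rows), outdir / "coloc.tsv", tag)
    links_df = pd.DataFrame([{
        "protein": e.protein, "trait": e.trait, "pp4": e.pp4, "variant": e.variant,
        "beta_protein": e.beta_protein, "beta_trait": e.beta_trait, "sign": e.sign,
    } for e in links])
    counts["accepted_links"] = _write_tsv(links_df, outdir / "links.tsv", tag)


def stage_network(config: RunConfig, outdir: Path, tag: str, counts: dict) -> None:
    links_df = _read_tsv(outdir / "links.tsv")
    links = [fc.ProteinTraitEdge(
        protein=r["protein"], trait=r["trait"], pp4=r["pp4"], variant=r["variant"],
        beta_protein=r["beta_protein"], beta_trait=r["beta_trait"],
    ) for _, r in links_df.iterrows()]
    G = fc.build_network(links)
    G.graph["run"] = tag
    fc.write_network(G, outdir / "network.tsv", outdir / "network.graphml")
    counts["network_nodes"] = G.number_of_nodes()
    counts["network_edges"] = G.number_of_edges()


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "exposures": stage_exposures,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "tissue-enrich": stage_tissue_enrich,
    "finemap": stage_finemap_coloc,   # finemap and coloc share one pass over regions
    "network": stage_network,
}


def run_all(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Any stage failure raises with a stage-tagged message; outputs of earlier
    stages are preserved on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}-s{config.seed}"
    counter = _WarningCounter()
    logging.getLogger("fastproteo").addHandler(counter)
    counts: dict = {}
    try:
        for stage in config.stages:
            if stage == "coloc":
                continue  # handled together with finemap
            func = _STAGE_FUNCS.get(stage)
            if func is None:
                raise ValueError(f"unknown stage {stage!r}")
            try:
                func(config, outdir, tag, counts)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("fastproteo").removeHandler(counter)
    manifest = {
        "run": tag,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": counts,
        "warnings": counter.count,
        "versions": {
            "fastproteo": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "config.yaml", "w") as fh:
        fh.write(config.to_yaml())
    return manifest
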