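"""Over-representation and specificity enrichment with redundancy pruning.

Significant proteins (or cluster members) are tested against gene-set
collections (KEGG/REACTOME-style GMT files) by the one-sided hypergeometric
tail, with all platform-covered protein-coding genes as the background
universe.  For figure-ready output, redundant pathways are pruned
iteratively: keep the set covering the most query genes, delete every set
that shares at least half of its own members with the kept one, repeat.

Tissue / cell-type specificity (Human-Protein-Atlas-style classes
"enhanced", "enriched", "group enriched") is tested per unit with a
two-sided Fisher exact test on significant × specific counts.

Multi-protein assays (protein complexes) are split into component genes
before gene-level analysis; when several assays target one gene, the record
with the lowest q-value is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trajectory_stats import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "map_assays",
    "overrepresentation",
    "prune_redundant",
    "specificity_enrichment",
    "SPECIFIC_CLASSES",
]

SPECIFIC_CLASSES = frozenset({"enhanced", "enriched", "group enriched"})


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, frozenset[str]]
    source: str = "custom"

    def __post_init__(self):
        clean = {}
        for sid, genes in self.sets.items():
            genes = frozenset(g for g in genes if g and str(g).strip())
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")
            clean[sid] = genes
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, name: str | None = None, source: str = "custom") -> GeneSetCollection:
    """GMT: one set per line — set_id <tab> description <tab> gene..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(name=name or str(path), sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for sid in collection.sets:
            genes = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{description or collection.source}\t{genes}\n")


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    query_size: int
    set_size: int
    background_size: int
    odds_ratio: float
    p: float
    q: float = np.nan
    retained: bool = True
    members: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Assay → gene mapping
# ---------------------------------------------------------------------------


def map_assays(assay_results: pd.DataFrame, id_map: dict[str, list[str]]) -> pd.DataFrame:
    """Gene-level results from assay-level results.

    Assays targeting several proteins (complexes) contribute one record per
    component gene; when multiple assays cover the same gene, only the record
    with the lowest q-value is kept.  Assays absent from `id_map` are dropped
    with a logged count.
    """
    if not id_map:
        raise ValueError("empty id_map")
    rows = []
    unmapped = 0
    for _, rec in assay_results.iterrows():
        genes = id_map.get(rec["assay_id"])
        if not genes:
            unmapped += 1
            continue
        for g in genes:
            row = rec.to_dict()
            row["gene"] = g
            rows.append(row)
    if unmapped:
        logger.warning("map_assays: dropped %d unmapped assays", unmapped)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values(["q", "assay_id"], kind="mergesort").drop_duplicates("gene", keep="first")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------


def overrepresentation(
    query: set[str], background: set[str], collection: GeneSetCollection
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of `query` in each gene set.

    Gene sets are intersected with the background before testing; the
    one-sided p is the upper hypergeometric tail P(overlap ≥ a) on the
    2×2 table.  q-values are BH-adjusted across the collection.
    """
    query, background = set(query), set(background)
    if not query:
        raise ValueError("empty query")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N, n = len(background), len(query)
    results = []
    for sid, genes in collection.sets.items():
        S = genes & background
        if not S:
            continue
        members = query & S
        a, K = len(members), len(S)
        p = float(sps.hypergeom.sf(a - 1, N, K, n))
        b, c, dd = K - a, n - a, N - K - n + a
        odds = (a * dd) / (b * c) if b * c > 0 else np.inf
        results.append(
            EnrichmentResult(
                set_id=sid, overlap=a, query_size=n, set_size=K,
                background_size=N, odds_ratio=odds, p=p, members=frozenset(members),
            )
        )
    if results:
        qs = adjust_bh(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# Redundancy pruning
# ---------------------------------------------------------------------------


def prune_redundant(
    results: list[EnrichmentResult],
    overlap_fraction: float = 0.5,
    coverage: str = "members",
) -> list[EnrichmentResult]:
    """Iterative pruning to a non-redundant subset of pathways.

    Loop: retain the candidate with the largest coverage (by default the
    number of significant query genes it contains; `coverage="set_size"` uses
    the full set size instead — the alternative reading), then delete every
    remaining candidate that shares at least `overlap_fraction` of *its own*
    members with the retained set; repeat until no candidates remain.  Ties
    break by smaller p, then lexicographic set id, so the result is a
    deterministic function of the input.  Retained flags are set in place and
    the full list is returned (same order as input).
    """
    if coverage not in ("members", "set_size"):
        raise ValueError("coverage must be 'members' or 'set_size'")
    for r in results:
        if r.members is None:
            raise ValueError(f"result {r.set_id} lacks a member gene list")
        r.retained = False
    candidates = list(results)
    while candidates:
        def sort_key(r: EnrichmentResult):
            cov = len(r.members) if coverage == "members" else r.set_size
            return (-cov, r.p, r.set_id)

        best = min(candidates, key=sort_key)
        best.retained = True
        survivors = []
        for r in candidates:
            if r is best:
                continue
            if len(r.members) == 0:
                continue  # nothing left to cover
            shared = len(r.members & best.members)
            if shared >= overlap_fraction * len(r.members):
                continue  # redundant with the retained set
            survivors.append(r)
        candidates = survivors
    return results


# ---------------------------------------------------------------------------
# Tissue / cell-type specificity enrichment
# ---------------------------------------------------------------------------


def specificity_enrichment(
    significant: dict[str, bool] | pd.Series,
    annotation: pd.DataFrame,
    unit_type: str = "tissue",
) -> pd.DataFrame:
    """Two-sided Fisher exact test of significance × specificity per unit.

    `significant` maps every gene in the universe to a True/False status;
    `annotation` has columns gene, unit, class with classes from the
    {enhanced, enriched, group enriched, none} vocabulary.  Genes may be
    specific to several units.  Units with no annotated genes are skipped.
    """
    if isinstance(significant, pd.Series):
        significant = significant.to_dict()
    bad = set(annotation["class"]) - (SPECIFIC_CLASSES | {"none"})
    if bad:
        raise ValueError(f"unknown specificity classes: {sorted(bad)}")
    genes = list(significant)
    sig = {g for g, s in significant.items() if s}
    spec_of_unit: dict[str, set[str]] = {}
    ann = annotation[annotation["class"].isin(SPECIFIC_CLASSES)]
    for unit, grp in ann.groupby("unit"):
        spec_of_unit[str(unit)] = set(grp["gene"]) & set(genes)
    rows = []
    for unit in sorted(spec_of_unit):
        specific = spec_of_unit[unit]
        if not specific:
            logger.warning("specificity_enrichment: unit %s has no annotated genes, skipped", unit)
            continue
        a = len(sig & specific)
        b = len(sig) - a
        c = len(specific) - a
        d = len(genes) - len(sig) - c
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({"unit": unit, "unit_type": unit_type, "n_sig_specific": a,
                     "n_sig_other": b, "n_nonsig_specific": c, "n_nonsig_other": d,
                     "odds_ratio": odds, "p": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = adjust_bh(df["p"].to_numpy())
    return df
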