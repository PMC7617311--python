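# fastproteo

Analysis toolkit for longitudinal plasma-proteomics studies of prolonged
fasting, built around the design of a 7-day water-only fast: ~12 participants
sampled at a pre-fast baseline (day −2), daily during fasting (days 1–7) and
after refeeding (day 10), with thousands of protein assays reported on a
relative log2 (NPX-like) scale.

The package implements the full analysis chain as a library plus a CLI:

1. **Trajectory testing** (`trajectory_stats`) — per-protein random-intercept
   linear mixed models
   `y_it = β_0 + Σ_t β_t·1[day=t] + u_i + ε_it`, fitted by REML, giving
   per-day contrasts β_t versus baseline in pre-fast SD units, a calibrated
   global "any change" F test, time×sex interaction LRTs, exposure
   associations (weight, 3-hydroxybutyrate, …) with crossed random
   intercepts, and Benjamini–Hochberg FDR control.
2. **Directional clustering** (`directional_clustering`) — significant
   proteins are mapped to unit vectors z/‖z‖ with z_t = β_t/SE_t and
   clustered with a von Mises–Fisher mixture plus a uniform noise component,
   fitted by EM; the number of temporal response profiles is chosen by the
   first plateau of the BIC over K = 1..20 and proteins are hard-assigned.
3. **Enrichment** (`set_enrichment`) — hypergeometric over-representation
   against GMT gene-set collections with iterative redundancy pruning
   (retain the pathway covering the most query genes, delete pathways
   sharing ≥ half of their members with it, repeat), plus two-sided Fisher
   tests of tissue/cell-type specificity classes.
4. **Proteogenomics** (`finemap_coloc`) — cis-region (±500 kb, extended MHC
   excluded) fine-mapping with a sum-of-single-effects model on z-scores and
   LD (credible sets with purity filtering, L selected by the largest set of
   independent lead pQTLs with pairwise r² < 0.25), five-hypothesis
   colocalization with Wakefield ABFs (priors p1 = p2 = 1e−4, p12 = 5e−6),
   both region-level and per credible-set pair, and a signed bipartite
   protein–trait network from links with PP(H4) ≥ 80% whose shared variant
   is a credible-set lead or a strong proxy (r² > 0.8).
5. **Synthetic data** (`synthetic_data`) — fully seeded generators for
   studies with nine planted temporal archetypes, null and noise proteins,
   left-censoring at a detection limit, sex effects, exposure tracks, and
   GWAS regions simulated under each colocalization hypothesis H0–H4 from
   z ~ N(Rλ, R), so every stage is testable with known ground truth.

## Worked example

```python
from fastproteo import synthetic_data as sd, trajectory_stats as ts
from fastproteo import directional_clustering as dc

cfg = sd.SimConfig(n_per_cluster=30, n_null=30, n_noise=5)   # 305 assays
matrix, truth = sd.generate_study(cfg, seed=77)
std, excluded = ts.standardize(matrix)
results, table = ts.fit_all_trajectories(std)

glob = table[table.term == "global"]
print("significant (q<0.05):", int((glob.q < 0.05).sum()), "of", len(glob))

dm = dc.build_direction_matrix(table, q_threshold=0.05)
k_star, models = dc.select_k(dm, k_max=12, seed=0)
print("selected clusters:", k_star, "| BIC at K*:", round(models[k_star].bic))
```

Output:

```
significant (q<0.05): 278 of 305
selected clusters: 9 | BIC at K*: -4028
```

278 assays change significantly during the fast (the 270 planted signal
assays, the 5 noise assays — which carry genuine but unstructured change —
and a handful of null false positives), and the BIC plateau recovers the
nine planted temporal archetypes.

The same analysis end-to-end, from a shell:

```sh
fastproteo run-all --seed 7 --outdir run7      # TSV/GraphML outputs + manifest.json
```

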