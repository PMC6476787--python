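# tundradiv

Multi-scale diversity analysis of hierarchical vascular-plant surveys along
altitude gradients, built for the nested tundra sampling design
(mountain ⊃ 1 km transect ⊃ 25 × 25 m station ⊃ 1 m² plot, with transects
placed in four elevation bands: 700–900, 900–1100, 1100–1300, >1300 m).
It is aimed at community ecologists who want the full chain — alpha
diversity, multi-scale beta diversity, metacommunity structure, and
altitude trend models — as one tested, scriptable pipeline, plus a
synthetic survey generator so every stage can be exercised without field
data.

## What it computes

* **Alpha diversity** — per-plot richness and logit-transformed cover;
  per-station scaled Shannon evenness J = H/ln S of pooled point-intercept
  counts (J = 1 perfectly even, J = 0 a single-species community).
* **Beta diversity** — each plot's distance to group centroids in
  principal-coordinate space built from the binary Bray–Curtis (Sørensen)
  dissimilarity 1 − 2|a∩b|/(|a|+|b|), at three spatial scales: station,
  transect, and altitude band across the landscape. Negative-eigenvalue
  axes are retained so squared dissimilarities are reproduced exactly.
* **Metacommunity structure** — NODF nestedness (0–100) under optimal and
  altitude-imposed orderings, and Barber's bipartite modularity
  Q = (1/m) Σ (B_ij − k_i d_j/m) δ(g_i, h_j) maximised by BRIM with
  adaptive module count and restarts; both compared against a null model
  that preserves species frequencies (1,000 randomised matrices,
  Z = (obs − mean)/SD, one-tailed empirical p).
* **Altitude trends** — mixed models with nested random intercepts:
  Gaussian (statsmodels MixedLM, ML) for cover/evenness/beta distance and
  a Laplace-ML Poisson GLMM (implemented here) for richness;
  linear-vs-quadratic likelihood-ratio tests, scale × altitude interaction,
  and Tukey-adjusted pairwise scale contrasts.

The core computational pieces are scikit-learn-style estimators
(`PrincipalCoordinates`, `CentroidBetaDiversity`, `BRIMModularity`,
`MixedAltitudeModel`) with thin module-level functions over them.

## Worked example

```python
import tundradiv as td
from tundradiv import pipeline

# simulate the 11-transect field design (one top transect unsampled)
sim = td.simulate_survey(td.SimulationConfig(seed=1835504127, drop_one_transect=True))
mat = sim.matrix()
print(mat.shape)                       # (275, 143)

dist = td.beta_diversity_all_scales(mat)
print(dist.groupby("scale")["distance"].mean().round(3).to_dict())
# {'landscape': 0.383, 'station': 0.319, 'transect': 0.363}

res = td.nodf(mat)                     # optimal ordering
print(round(res.nodf, 2))              # 42.05
q = td.brim_optimize(mat, n_restarts=20, seed=1731038949)
print(round(q.Q, 3), q.n_modules)      # 0.245 4

plot_tbl, _ = pipeline.alpha_tables(sim.records, sim.intercepts)
fit = td.MixedAltitudeModel("cover_logit", 2, "gaussian").fit(plot_tbl)
print(round(fit.peak_altitude_))       # 846
```

Beta diversity rises from the station through the transect to the
landscape scale — compositional variation accumulates with spatial extent;
the fitted cover optimum (846 m) recovers the generator's true peak
(850 m); and both nestedness and modularity come out far above their
null expectations when tested (see the acceptance run below).

The same analysis runs from a shell:

```bash
tundradiv run --simulate --seed 7 --reps 200 --out out/
tundradiv run --config examples/simulated-run.yaml
```

which writes `alpha_plots.csv`, `alpha_evenness.csv`, `beta_distances.csv`,
`trend_models.csv`, `lrt.csv`, `scale_contrasts.csv`, `metacommunity.csv`,
incidence-matrix images, and a run log; every table header records the
seed and config hash.

## Using your own data

Long-format plot records are CSV with columns
`mountain,transect,station,plot,altitude_m,cover,species` (semicolon-
separated species list; cover as percent or proportion, auto-detected), or
wide form with one 0/1 column per species. A pre-built presence–absence
matrix is CSV with the four metadata columns
`mountain,transect,station,plot,altitude_m` followed by one 0/1 column per
species — map an external deposit to this shape (one row per 1 m² plot,
plot metadata in the leading columns) and pass it with `--matrix`;
`keep_empty_species=True` preserves all-zero species columns for exact
round-tripping. Intercept counts are long-form `station,species,count`.
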