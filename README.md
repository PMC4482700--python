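# nichedrift

Coupled **ecological niche modelling** and **Lagrangian larval-dispersal
analysis** for coastal species whose spread is limited jointly by climate and
ocean currents — the classic situation of a marine invader (e.g. the mussel
*Mytilus galloprovincialis* in southern Africa) whose range edges sit where
thermal regimes change and where oceanographic fronts block larval transport.

The package answers three questions with one reproducible pipeline:

1. **Where is habitat suitable?** An ensemble of boosted-regression-tree (BRT)
   niche models is built from presence records and environmental predictor
   rasters. Pseudo-absences (one per presence) are drawn from cells whose
   Mahalanobis-distance suitability, `1 − F_χ²(D²; df = p)`, falls below 0.2.
   Every predictor subset passing a pairwise Spearman collinearity filter
   (|ρ| < 0.7) is a candidate; each is tuned by inner 10-fold CV deviance over
   learning rates {0.1 … 0.001}, tree complexities 1…p and tree counts
   100–10000 (minimum 1000, bag fraction 0.5), and scored over 30 repeated
   70/30 splits by the True Skill Statistic (TSS = sensitivity + specificity
   − 1) at the threshold maximising sensitivity + specificity. Candidates are
   ranked by mean TSS and accumulated into a Kruskal–Wallis test until the
   first significant addition (α = 0.05); the preceding, statistically
   indistinguishable set is refitted on all records and merged cell-wise by
   the median (SD = uncertainty), then reclassified to a binary range map.
2. **Has the niche diverged between ranges?** The z-scored environmental
   conditions at presences are projected on principal components; PERMANOVA
   (Anderson's distance-based pseudo-F on Euclidean distances) tests for a
   centroid shift between native and non-native ranges and PERMDISP (ANOVA F
   on distances to group centroids, centroids recomputed per permutation) for
   a dispersion difference, each with permutation p-values.
3. **Can larvae get past the range edge?** Passive particles are released
   daily from every coastal cell through the spawning season, advected every
   2 h through daily (u, v) current fields with bilinear interpolation, and
   tracked for a pelagic larval duration (PLD) of 30 or 90 days. Connectivity
   `C[i][j]` = fraction of simulated steps that particles from cell *i* spent
   in cell *j* (diagonal = retention). Annual matrices are averaged, PLDs
   compared by a Mantel test over all off-diagonal cells, and dispersal
   barriers located as cut points of the graph with edges `C[i][j] > 0.05`.

Everything runs on synthetic data with known ground truth (module
`nichedrift.synthdata`): thermal-envelope species on latitudinal gradients,
idealised coastlines, and coast-parallel jets with an offshore-deflection
front and optional inshore counter-current — or on any conforming occurrence
CSV, predictor/velocity NetCDF you supply.

## Worked example

Generate the standard fixture set and run the full pipeline:

```bash
nichedrift make-fixtures --out fixtures --seed 11
nichedrift pipeline --config config.yaml --seed 3 --out runs/demo
```

with a `config.yaml` like

```yaml
occurrences: fixtures/occurrences.csv
predictors: [fixtures/sst_extreme.nc, fixtures/salinity_extreme.nc]
velocity: fixtures/velocity.nc
coastline: fixtures/coastline.csv
stages: [enm, divergence, lps]
enm: {n_cv_runs: 5, learning_rates: [0.1], n_trees_grid: [1000], inner_cv_folds: 3}
lps: {years: [2008], spawning_months: [5]}
divergence: {n_perm: 999}
```

The JSON report printed at the end contains, among others (values from a run
of exactly this configuration at seed 3 on the seed-11 fixtures):

```text
"selected": [["sst_extreme"], ["sst_extreme", "salinity_extreme"]]
"ensemble_fit_tss": 0.914        # TSS of the binary map on its fitting records
"survey_sensitivity": 0.942      # surveyed presences inside the predicted range
"survey_specificity": 1.0        # no survey absence is over-predicted
"permanova_p": 0.817             # no centroid shift between ranges
"permdisp_f": 49.02, "permdisp_p": 0.001   # invaded range uses a narrower
                                 # part of the native environmental space
"mantel_r_pld30_vs_90": 0.707    # 30- vs 90-day connectivity strongly agree
"barriers_up": [45, ...]         # first dispersal cut exactly at the imposed
                                 # front (above coastal cell 45)
```

i.e. the framework recovers the planted thermal envelope (the temperature
predictor scores univariate TSS 0.87 vs 0.06 for the distractor), detects
niche *narrowing* rather than divergence, and places the dispersal barrier at
the velocity front it was given.

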