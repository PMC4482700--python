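# Methods

This note documents the models, numerical conventions and design choices
behind `nichedrift`, and what the synthetic-data experiments do and do not
demonstrate.

## Spatial conventions

All stages share one grid convention (`gridio.GridSpec`): a regular lon/lat
grid of cell size `cell_size` (default 0.08°), with 0-based cells spanning
half-open intervals `[edge, edge + cell_size)`. A point exactly on a cell's
upper edge belongs to the next cell; the same rule maps occurrence records,
particle positions and coastal-cell ids, so no point can be double-counted.
Occurrence records are snapped to this grid with at most one record per cell
(duplicates collapse; a presence/absence conflict inside one cell resolves to
presence, because only presences enter the presence-only models and survey
absences are reserved for validation). Value arrays are `[lat, lon]`; missing
cells are NaN, never zero.

Degrees convert to meters as 111,320 m per degree latitude and
`111,320·cos(lat)` per degree longitude, shared between the velocity-field
generators and the particle integrator so that generated speeds and advected
displacements are consistent.

## Niche-model ensemble

**Pseudo-absences.** Habitat suitability for the pseudo-absence pool is
`1 − F_χ²(D²; df = p)` where `D²` is the squared Mahalanobis distance of a
cell's (internally z-scored) predictor vector to the presence mean under the
presence covariance. The χ² survival function was chosen because it maps `D²`
to a bounded, monotone [0, 1] score with an exact probabilistic reading when
the presence cloud is Gaussian. Pseudo-absences are sampled uniformly,
without replacement, from cells with suitability < 0.2 holding no presence;
their count equals the presence count. Survey absences never enter fitting.

**Candidates and tuning.** Candidate models are all predictor subsets whose
pairwise Spearman |ρ| (over jointly valid cells) stays below 0.7. Each
candidate is a stochastic gradient-boosted tree classifier (binomial
deviance, bag fraction 0.5); "tree complexity" is realised as the maximum
depth of each boosting tree, the closest portable analogue of interaction
order. Hyperparameters — learning rate, depth (1…subset size), tree count —
are selected by inner stratified k-fold CV: for each (rate, depth) the model
is grown once per fold to the largest count in the grid and held-out deviance
is read off the staged predictions at every grid count, so the search costs
one fit per (rate, depth, fold). The tree count is constrained to at least
`min_trees` (default 1000); if no eligible grid point has finite CV deviance
the best available fit is returned with a warning. Grid order is
deterministic (rates descending, depth ascending, count ascending) so ties
resolve identically across runs.

**Evaluation and selection.** The outer loop repeats `n_cv_runs` times:
fresh pseudo-absences, independent 70/30 splits of presences and
pseudo-absences, all candidates fitted on the same split, test-set TSS at the
threshold (searched over observed scores only, ties to the lowest) maximising
sensitivity + specificity. Candidates are ranked by mean TSS; a Kruskal–Wallis
test is grown from the top down and selection stops *before* the first
addition making p ≤ α — the selected prefix is the largest set whose
accuracies are statistically indistinguishable. The direction of that rule
(exclude the triggering addition) was an open choice; excluding it is the
conservative reading. Selected candidates are refitted on all records with a
fresh pseudo-absence draw; the cell-wise median across members is the
ensemble suitability, the cell-wise SD its uncertainty, and the final binary
map thresholds the median at the sensitivity+specificity optimum over
presences and pseudo-absences.

**Importance.** Per predictor: the mean TSS of its singleton candidate
(univariate effect), and the mean over candidate pairs (C, C∖{x}) of the
difference of their mean TSS (gain when added to other predictors).

## Niche divergence

Environmental vectors at presences are z-scored (making the PCA one of the
correlation structure); component signs are fixed by forcing each loading
vector's largest-magnitude element positive, for backend-independent
reproducibility. The first two component scores (configurable) feed both
tests. PERMANOVA uses Anderson's distance-based pseudo-F on Euclidean
distances,

    SS_T = (1/N) Σ_{i<j} d²_ij,   SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
    F = ((SS_T − SS_W)/(a−1)) / (SS_W/(N−a)),

which reduces exactly to the classical one-way ANOVA F in one dimension (a
tested identity). PERMDISP computes each point's Euclidean distance to its
group *centroid* (not the spatial median — the centroid matches the distance
geometry of the PCA space and is recomputed under every permutation) and
takes the one-way ANOVA F of those distances. Both tests permute group
labels; p-values use the add-one rule `p = (1 + #{perm ≥ obs})/(n_perm + 1)`
so p is never 0 and never below `1/(n_perm+1)`. An exhaustive-enumeration
mode exists for tiny samples and reports the exact fraction including the
identity.

A joint reading of the two tests: non-significant PERMANOVA with strongly
significant PERMDISP indicates the non-native population occupies a
*narrower part* of the native environmental space, not a shifted niche.

## Permutation statistics

TSS, Spearman (Pearson on mid-ranks, average ranks for ties), Kruskal–Wallis
(tie-corrected H, χ² p with k−1 df) and the Mantel test are implemented
in-package because their exact conventions propagate into model selection and
matrix comparison. The Mantel statistic is the Pearson correlation over *all*
off-diagonal entries — connectivity matrices are directed, so both triangles
carry information; symmetric inputs reduce to the classical statistic — and
the null permutes one relabelling applied simultaneously to rows and columns
of the second matrix. The test is one-sided toward positive correlation, the
relevant alternative when asking whether two connectivity patterns resemble
each other.

Calibration under a true null is part of the test suite: over 500 null
replicates with 199 permutations each, the empirical rejection rate of each
test at the conventional levels 0.01/0.05/0.10 must sit within ±0.03 of
nominal. (A full Kolmogorov–Smirnov sup-norm is deliberately not used as the
pass criterion: its own sampling noise at 500 draws averages ≈0.04, so it
would reject a perfectly calibrated test most of the time.)

## Particle simulation

Particles are released from coastal-cell centers daily through the spawning
season (default May–July and October–January, with January attributed to the
calendar year containing it: 215 release days per cell per non-leap year) and
advected with forward Euler at 2-hour steps (12/day) for the configured PLD
(30 or 90 days). Velocities come from bilinear interpolation of the day's
(u, v) cell-center fields; daily fields are held piecewise-constant in time,
matching the daily cadence of the source product. Missing (land) neighbours
contribute nothing and the remaining bilinear weights are renormalised; a
step whose endpoint falls on a land cell is cancelled (the particle holds
position for that step), and a particle leaving the grid bounds — or
outliving the velocity series — stops accruing steps. Forward Euler is the
default because only the step length and interpolation are part of the
simulation design; a classical RK4 update is available behind
`integrator="rk4"` and is used in convergence tests. On a solid-body rotation
with period 10 days, Euler's analytic outward drift per revolution,
`(1+(ωΔt)²)^(N/2) − 1` ≈ 17.9 % of the radius at 2-hour steps, is reproduced
to better than 1 %, and the error halves when the step halves (order 1); RK4
reduces it by orders of magnitude.

Connectivity `C[i][j]` divides the total steps particles from cell *i* spent
in coastal cell *j* by `n_particles_i × pld_days × 12`; steps spent in
non-coastal water count only in the denominator, so row sums are ≤ 1 with
equality only if every step of every particle stays on the coastal strip.
The diagonal is larval retention. Annual matrices are averaged element-wise.
Stepping-stone reach is the transitive closure of the directed graph with
edges `C[i][j] > 0.05` (strict, matching the probability wording of the
threshold); a dispersal barrier is the cut between adjacent coastal cells
(k, k+1) where no cell ≤ k connects above threshold to any cell ≥ k+1 in the
stated direction.

## Synthetic study conditions

The generators (`synthdata`) are pure functions of parameters and seed and
define the default experimental conditions:

* **Environmental domain** — 40 × 120 cells at 0.2°, temperature decreasing
  poleward at 0.667 °C per degree latitude (≈10–26 °C across the domain),
  treated as an exactly known climatological layer (no measurement noise);
  one distractor predictor of pure seeded noise (sd 1).
* **Species** — thermal envelope [15, 22] °C with logistic edges of width
  0.1 °C and full detection; 500 presences sampled ∝ suitability without
  replacement, 200 survey absences outside the envelope. Range labels are
  assigned by region: the non-native (invaded) region is the eastern half of
  the domain restricted to a central latitude band of the envelope
  (≈16–20 °C), so its environmental conditions are nested inside the native
  ones — the scenario in which a sound analysis should report no niche
  divergence (PERMANOVA ns) but a narrower invaded niche (PERMDISP
  significant).
* **Dispersal domain** — a 14 × 70-cell strip at 0.08° with a meridional
  coast of 60 cells (land to the east); a coast-parallel jet of 0.15 m/s
  whose speed tapers to 15 % in the coastal column (so nearshore residence,
  hence retention, is realistic), an offshore-deflection front above coastal
  cell 45 where alongshore flow dies and a 0.15 m/s seaward component
  appears, optionally an inshore counter-current of 0.02 m/s opposing the
  jet, and per-day, per-cell Gaussian noise before land masking.

Reduced problem sizes used by the test suite and the acceptance script —
5 cross-validation repeats, learning-rate grid {0.1}, tree grid {1000} (the
minimum-tree rule intact), 3 inner folds, one month of daily releases — keep
a full recovery experiment within minutes while leaving every structural rule
of the framework in force; the full-size defaults remain on the config
objects.

**What passing these experiments shows** — that the pipeline's machinery is
correct: the framework recovers a planted envelope to within a cell, ranks
the causal predictor first, the permutation tests are exact/calibrated, the
integrator converges, and the barrier detector finds the front it was given.
**What it does not show** — performance on real data: the synthetic fields
have no mesoscale turbulence, eddies or fronts beyond the imposed jet
structure, no spatial autocorrelation in the distractor predictors, no
detection bias or georeferencing error in surveys, and passive particles with
no larval behaviour (no vertical migration, mortality or settlement
competency). Conclusions about a real species require the corresponding real
predictor and current products.

## Known limitations

* The Euler integrator at 2-hour steps systematically inflates curved
  trajectories (see above); for strongly rotational flows use `rk4`.
* PERMDISP assumes exchangeability under the null; with grossly unbalanced
  groups and location shifts its F can confound shift and spread.
* The Mahalanobis suitability assumes an ellipsoidal presence cloud; heavily
  multimodal niches would need a different pseudo-absence screen.
* `pld_days × 24` must be divisible by `step_hours`; daily fields are not
  interpolated sub-daily.
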