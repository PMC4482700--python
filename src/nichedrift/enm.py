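"""Ecological niche modelling with transferability-based ensemble selection.

The framework models presence records against environmental predictor
rasters using boosted regression trees (BRT), with the emphasis on
*transferability* — selecting predictor combinations whose accuracy
holds up on records not used for fitting:

1. a Mahalanobis-distance suitability surface over the predictor space
   locates the species' ecological domain; pseudo-absences (as many as
   there are presences) are drawn from cells with suitability below a
   0.2 cutoff;
2. every combination of predictors passing a pairwise Spearman
   collinearity filter (|rho| < 0.7) is a candidate model;
3. each candidate is fitted as a BRT (binomial deviance, stochastic bag
   fraction 0.5) with learning rate, tree complexity (maximum tree
   depth) and tree count tuned by inner k-fold cross-validated deviance,
   enforcing a minimum tree count;
4. an outer loop of repeated 70/30 train/test splits — pseudo-absences
   re-drawn every repeat — scores each candidate by the True Skill
   Statistic at the threshold maximising sensitivity + specificity;
5. candidates are ranked by mean TSS and accumulated into a
   Kruskal-Wallis test until the first addition that makes the test
   significant; the preceding set (statistically indistinguishable
   accuracy) forms the ensemble;
6. selected candidates are refitted on the full record set; their
   per-cell median is the ensemble suitability map, their per-cell SD
   its uncertainty, and a final sensitivity+specificity-maximising
   threshold reclassifies the median into a binary range map, which can
   be validated against independent survey presences *and* absences.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, xlogy
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .gridio import OccurrenceSet, Raster2D
from .stats_core import (
    EvaluationResult,
    best_threshold_max_sens_plus_spec,
    kruskal_wallis,
    spearman_rho,
    tss_at_threshold,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ENMConfig:
    """Framework settings; defaults follow the study design."""

    pa_suitability_threshold: float = 0.2
    train_fraction: float = 0.7
    n_cv_runs: int = 30
    spearman_cutoff: float = 0.7
    learning_rates: tuple[float, ...] = (0.1, 0.05, 0.01, 0.005, 0.001)
    n_trees_grid: tuple[int, ...] = tuple(range(100, 10001, 50))
    min_trees: int = 1000
    bag_fraction: float = 0.5
    inner_cv_folds: int = 10
    kw_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not self.learning_rates or not self.n_trees_grid:
            raise ValueError("hyperparameter grids must be nonempty")


@dataclass
class CandidateModel:
    """A fitted predictor-subset model with its tuned hyperparameters."""

    subset: tuple[str, ...]
    model: GradientBoostingClassifier
    learning_rate: float
    tree_complexity: int
    n_trees: int

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


@dataclass
class CVResults:
    """Per-combo TSS score lists from the repeated-split framework."""

    combos: list[tuple[str, ...]]
    scores: dict[tuple[str, ...], list[float]]
    failures: dict[tuple[str, ...], list[str]] = field(default_factory=dict)

    def mean_scores(self) -> dict[tuple[str, ...], float]:
        return {c: float(np.mean(s)) for c, s in self.scores.items() if s}

    def ranked(self) -> list[tuple[str, ...]]:
        """Combos by decreasing mean TSS (ties broken by name for determinism)."""
        means = self.mean_scores()
        return sorted(means, key=lambda c: (-means[c], c))


@dataclass
class EnsembleResult:
    median: Raster2D
    sd: Raster2D
    binary: Raster2D
    threshold: float
    members: list[CandidateModel]
    evaluation: EvaluationResult


# ---------------------------------------------------------------------------
# predictor-stack helpers
# ---------------------------------------------------------------------------

def stack_matrix(predictors: list[Raster2D]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-predictors-valid cells as a matrix.

    Returns ``(X, iy, ix)``: the (n_cells, p) value matrix and the grid
    indices of each row.
    """
    if not predictors:
        raise ValueError("empty predictor stack")
    grid = predictors[0].grid
    for r in predictors:
        if r.grid != grid:
            raise ValueError("predictors must share one grid")
    mask = np.logical_and.reduce([r.mask for r in predictors])
    iy, ix = np.nonzero(mask)
    X = np.column_stack([r.values[iy, ix] for r in predictors])
    return X, iy, ix


def env_at_points(predictors: list[Raster2D], lon, lat) -> np.ndarray:
    cols = [r.value_at(lon, lat) for r in predictors]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# pseudo-absence machinery
# ---------------------------------------------------------------------------

def mahalanobis_suitability(occ: OccurrenceSet, predictors: list[Raster2D]) -> Raster2D:
    """Habitat suitability from the Mahalanobis distance to the presence cloud.

    Predictors are z-scored internally; the squared distance D2 of each
    cell to the presence mean under the presence covariance is mapped to
    ``suitability = 1 - F_chi2(D2; df = n_predictors)``, the chi-square
    survival function — 1 at the presence centroid, decaying
    monotonically with environmental distance.
    """
    X, iy, ix = stack_matrix(predictors)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor in stack")
    Z = (X - mu) / sd
    pres = occ.presences
    P = (env_at_points(predictors, pres["lon"].to_numpy(), pres["lat"].to_numpy()) - mu) / sd
    P = P[np.isfinite(P).all(axis=1)]
    p = len(predictors)
    if P.shape[0] < p + 1:
        raise ValueError("need more presences than predictors for a covariance estimate")
    cov = np.cov(P, rowvar=False, ddof=1).reshape(p, p)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular presence covariance; consider removing a redundant predictor"
        ) from err
    centered = Z - P.mean(axis=0)
    w = np.linalg.solve(chol, centered.T)
    d2 = np.einsum("ij,ij->j", w, w)
    suit = sps.chi2.sf(d2, df=p)
    grid = predictors[0].grid
    values = np.full(grid.shape, np.nan)
    values[iy, ix] = suit
    return Raster2D(grid, values, name="mahalanobis_suitability", units="probability")


def sample_pseudo_absences(suitability: Raster2D, occ: OccurrenceSet,
                           config: ENMConfig, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample (without replacement) of pseudo-absence cell centers.

    The eligible pool is every cell with suitability below the config
    threshold that holds no presence record; the sample size equals the
    presence count.  Survey absences play no role here — they are
    reserved for independent validation.
    """
    grid = suitability.grid
    pres = occ.presences
    n_presence = len(pres)
    pool_mask = suitability.mask & (suitability.values < config.pa_suitability_threshold)
    px, py = grid.cell_index(pres["lon"].to_numpy(), pres["lat"].to_numpy())
    ok = px >= 0
    pool_mask[py[ok], px[ok]] = False
    iy, ix = np.nonzero(pool_mask)
    if iy.size == 0:
        raise ValueError("no cells below the pseudo-absence suitability threshold")
    if iy.size < n_presence:
        raise ValueError(
            f"pseudo-absence pool has {iy.size} cells but {n_presence} are required"
        )
    sel = rng.choice(iy.size, size=n_presence, replace=False)
    lon = grid.lon_min + (ix[sel] + 0.5) * grid.cell_size
    lat = grid.lat_min + (iy[sel] + 0.5) * grid.cell_size
    return lon, lat


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_predictor_combos(predictors: list[Raster2D],
                               cutoff: float = 0.7) -> list[tuple[str, ...]]:
    """Every nonempty predictor subset free of strong pairwise correlation.

    Pairwise Spearman |rho| is computed over the cells where both
    predictors are valid; a subset qualifies when all its pairs are
    below the cutoff.
    """
    names = [r.name for r in predictors]
    if len(set(names)) != len(names):
        raise ValueError("predictor names must be unique")
    p = len(predictors)
    ok_pair = np.ones((p, p), dtype=bool)
    for a, b in itertools.combinations(range(p), 2):
        both = predictors[a].mask & predictors[b].mask
        rho = spearman_rho(predictors[a].values[both], predictors[b].values[both])
        ok_pair[a, b] = ok_pair[b, a] = abs(rho) < cutoff
    combos = []
    for r in range(1, p + 1):
        for subset in itertools.combinations(range(p), r):
            if all(ok_pair[a, b] for a, b in itertools.combinations(subset, 2)):
                combos.append(tuple(names[i] for i in subset))
    return combos


# ---------------------------------------------------------------------------
# boosted-tree fitting
# ---------------------------------------------------------------------------

def _cv_deviance(y_true: np.ndarray, raw_score: np.ndarray) -> float:
    """Mean binomial deviance from log-odds scores."""
    p = expit(raw_score)
    return float(-2.0 * np.mean(xlogy(y_true, p) + xlogy(1 - y_true, 1 - p)))


def fit_boosted_trees(X: np.ndarray, y: np.ndarray, subset: tuple[str, ...],
                      config: ENMConfig, rng: np.random.Generator) -> CandidateModel:
    """Fit one BRT candidate with inner-CV hyperparameter tuning.

    For each (learning rate, tree complexity) the model is grown once
    per fold to the largest tree count in the grid; held-out binomial
    deviance is evaluated at every grid count via staged predictions,
    and the (rate, complexity, count) triple minimising mean CV deviance
    — subject to the minimum-tree-count rule — is refitted on the full
    training data.  Ties resolve by the deterministic grid order
    (sorted rates descending, complexity ascending, count ascending).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        raise ValueError("need at least 10 records per class")
    n_trees_grid = np.asarray(sorted(config.n_trees_grid))
    max_trees = int(n_trees_grid.max())
    depths = range(1, len(subset) + 1)
    rates = sorted(config.learning_rates, reverse=True)
    fold_seed = int(rng.integers(2**31 - 1))
    fit_seed = int(rng.integers(2**31 - 1))
    n_folds = min(config.inner_cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    splits = list(skf.split(X, y))

    results = []  # (mean_dev, rate_order, depth, n_trees)
    for ri, lr in enumerate(rates):
        for depth in depths:
            dev = np.zeros(len(n_trees_grid))
            for tr_idx, va_idx in splits:
                gbc = GradientBoostingClassifier(
                    learning_rate=lr, n_estimators=max_trees, max_depth=depth,
                    subsample=config.bag_fraction, random_state=fit_seed,
                )
                gbc.fit(X[tr_idx], y[tr_idx])
                staged = np.vstack([s.ravel() for s in
                                    gbc.staged_decision_function(X[va_idx])])
                for gi, nt in enumerate(n_trees_grid):
                    dev[gi] += _cv_deviance(y[va_idx], staged[nt - 1])
            dev /= len(splits)
            for gi, nt in enumerate(n_trees_grid):
                results.append((dev[gi], ri, depth, int(nt)))

    eligible = [r for r in results if r[3] >= config.min_trees and np.isfinite(r[0])]
    if not eligible:
        warnings.warn(
            "no tuning grid point reaches the minimum tree count with finite CV "
            "deviance; returning the best available fit", stacklevel=2)
        eligible = [r for r in results if np.isfinite(r[0])] or results
    eligible.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    best_dev, ri, depth, n_trees = eligible[0]
    model = GradientBoostingClassifier(
        learning_rate=rates[ri], n_estimators=n_trees, max_depth=depth,
        subsample=config.bag_fraction, random_state=fit_seed,
    )
    model.fit(X, y)
    return CandidateModel(subset=subset, model=model, learning_rate=rates[ri],
                          tree_complexity=depth, n_trees=n_trees)


# ---------------------------------------------------------------------------
# repeated-split framework
# ---------------------------------------------------------------------------

def _split_7030(n: int, frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    cut = int(round(frac * n))
    return idx[:cut], idx[cut:]


def run_cv_framework(occ: OccurrenceSet, predictors: list[Raster2D],
                     combos: list[tuple[str, ...]], config: ENMConfig) -> CVResults:
    """Repeated 70/30 evaluation of every candidate combination.

    Each repeat draws fresh pseudo-absences, splits presences and
    pseudo-absences 70/30 independently, fits every combination on the
    same split and scores it by test-set TSS at the
    sensitivity+specificity-maximising threshold.  Fitting failures are
    recorded per combination without aborting the repeat.
    """
    name_to_col = {r.name: k for k, r in enumerate(predictors)}
    suit = mahalanobis_suitability(occ, predictors)
    pres = occ.presences
    X_pres = env_at_points(predictors, pres["lon"].to_numpy(), pres["lat"].to_numpy())
    keep = np.isfinite(X_pres).all(axis=1)
    X_pres = X_pres[keep]

    master = np.random.default_rng(config.seed)
    scores: dict[tuple[str, ...], list[float]] = {c: [] for c in combos}
    failures: dict[tuple[str, ...], list[str]] = {c: [] for c in combos}
    for run in range(config.n_cv_runs):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        pa_lon, pa_lat = sample_pseudo_absences(suit, occ, config, rng)
        X_pa = env_at_points(predictors, pa_lon, pa_lat)
        tr_p, te_p = _split_7030(len(X_pres), config.train_fraction, rng)
        tr_a, te_a = _split_7030(len(X_pa), config.train_fraction, rng)
        X_train = np.vstack([X_pres[tr_p], X_pa[tr_a]])
        y_train = np.concatenate([np.ones(len(tr_p), int), np.zeros(len(tr_a), int)])
        X_test = np.vstack([X_pres[te_p], X_pa[te_a]])
        y_test = np.concatenate([np.ones(len(te_p), int), np.zeros(len(te_a), int)])
        for combo in combos:
            cols = [name_to_col[n] for n in combo]
            try:
                cand = fit_boosted_trees(X_train[:, cols], y_train, combo, config, rng)
                pred = cand.predict_suitability(X_test[:, cols])
                _, ev = best_threshold_max_sens_plus_spec(pred, y_test)
                scores[combo].append(ev.tss)
            except Exception as err:  # keep the run going, record the failure
                failures[combo].append(f"run {run}: {err}")
                logger.warning("combo %s failed on run %d: %s", combo, run, err)
    return CVResults(combos=list(combos), scores=scores,
                     failures={c: f for c, f in failures.items() if f})


def select_transferable(cv: CVResults, kw_alpha: float = 0.05) -> list[tuple[str, ...]]:
    """Largest prefix of TSS-ranked combos with indistinguishable accuracy.

    Combos are sorted by decreasing mean TSS; starting from the top one,
    the next-ranked combo is added and a Kruskal-Wallis test run over
    all included score lists, stopping right before the addition that
    first reaches significance.
    """
    ranked = cv.ranked()
    if not ranked:
        raise ValueError("no scored combinations to select from")
    selected = [ranked[0]]
    for combo in ranked[1:]:
        trial = [cv.scores[c] for c in selected] + [cv.scores[combo]]
        if kruskal_wallis(trial).p_value <= kw_alpha:
            break
        selected.append(combo)
    return selected


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def build_ensemble(selected: list[tuple[str, ...]], occ: OccurrenceSet,
                   predictors: list[Raster2D], config: ENMConfig) -> EnsembleResult:
    """Refit the selected combinations on the full record set and merge.

    The per-cell median across members is the ensemble suitability, the
    per-cell SD its uncertainty; the binary map thresholds the median at
    the sensitivity+specificity-maximising value over presences and a
    fresh pseudo-absence draw.
    """
    if not selected:
        raise ValueError("empty model selection")
    name_to_col = {r.name: k for k, r in enumerate(predictors)}
    grid = predictors[0].grid
    suit = mahalanobis_suitability(occ, predictors)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31 - 1))
    pres = occ.presences
    X_pres = env_at_points(predictors, pres["lon"].to_numpy(), pres["lat"].to_numpy())
    keep = np.isfinite(X_pres).all(axis=1)
    X_pres = X_pres[keep]
    pa_lon, pa_lat = sample_pseudo_absences(suit, occ, config, rng)
    X_pa = env_at_points(predictors, pa_lon, pa_lat)
    X_all = np.vstack([X_pres, X_pa])
    y_all = np.concatenate([np.ones(len(X_pres), int), np.zeros(len(X_pa), int)])

    X_cells, iy, ix = stack_matrix(predictors)
    members, maps, fit_preds = [], [], []
    for combo in selected:
        cols = [name_to_col[n] for n in combo]
        cand = fit_boosted_trees(X_all[:, cols], y_all, combo, config, rng)
        members.append(cand)
        maps.append(cand.predict_suitability(X_cells[:, cols]))
        fit_preds.append(cand.predict_suitability(X_all[:, cols]))

    stackmaps = np.vstack(maps)
    median_cells = np.median(stackmaps, axis=0)
    sd_cells = np.std(stackmaps, axis=0, ddof=0)
    median_fit = np.median(np.vstack(fit_preds), axis=0)
    threshold, ev = best_threshold_max_sens_plus_spec(median_fit, y_all)

    def to_raster(cells: np.ndarray, name: str) -> Raster2D:
        vals = np.full(grid.shape, np.nan)
        vals[iy, ix] = cells
        return Raster2D(grid, vals, name=name, units="probability")

    binary = to_raster((median_cells >= threshold).astype(float), "binary_range")
    return EnsembleResult(
        median=to_raster(median_cells, "ensemble_median"),
        sd=to_raster(sd_cells, "ensemble_sd"),
        binary=binary,
        threshold=float(threshold),
        members=members,
        evaluation=ev,
    )


# ---------------------------------------------------------------------------
# importance & validation
# ---------------------------------------------------------------------------

def predictor_importance(cv: CVResults) -> pd.DataFrame:
    """Univariate TSS and mean accuracy gain per predictor.

    The univariate column is the mean TSS of the predictor's singleton
    combination; the gain column averages, over every combination
    containing the predictor whose reduced combination (same predictors
    minus this one) was also evaluated, the difference of their mean
    TSS.  Predictors lacking any valid pairing get NaN in that column.
    """
    means = {c: float(np.mean(s)) for c, s in cv.scores.items() if s}
    names = sorted({n for c in cv.combos for n in c})
    rows = []
    for name in names:
        uni = means.get((name,), np.nan)
        gains = []
        for combo in cv.combos:
            if name in combo and len(combo) > 1:
                reduced = tuple(n for n in combo if n != name)
                if combo in means and reduced in means:
                    gains.append(means[combo] - means[reduced])
        rows.append({"predictor": name, "univariate_tss": uni,
                     "mean_gain": float(np.mean(gains)) if gains else np.nan})
    return pd.DataFrame(rows).set_index("predictor")


def validate_against_surveys(binary: Raster2D, surveys: OccurrenceSet) -> EvaluationResult:
    """Confusion of the binary range map against survey presences/absences.

    Survey points off the grid or on missing cells are excluded with a
    logged count.
    """
    lon = surveys.records["lon"].to_numpy()
    lat = surveys.records["lat"].to_numpy()
    pred = binary.value_at(lon, lat)
    ok = np.isfinite(pred)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("validate_against_surveys: %d survey point(s) off-grid or on "
                       "missing cells were excluded", n_dropped)
    labels = surveys.records["occurrence"].to_numpy()[ok]
    return tss_at_threshold(pred[ok], labels, 0.5)
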