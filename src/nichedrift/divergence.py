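"""Niche divergence between native and non-native ranges.

The environmental conditions at presence records are projected onto
principal components of the z-scored predictor matrix; location and
dispersion differences between ranges in that reduced space are then
tested by permutation:

* PERMANOVA — distance-based pseudo-F for a location (centroid) shift,
  computed on Euclidean distances with

      SS_T = (1/N) * sum_{i<j} d_ij^2
      SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
      F    = ((SS_T - SS_W) / (a - 1)) / (SS_W / (N - a))

  which for univariate data coincides exactly with the classical one-way
  ANOVA F.
* PERMDISP — one-way ANOVA F on each point's Euclidean distance to its
  group centroid, with centroids (and distances) recomputed under every
  label permutation.

A significant PERMANOVA with a significant PERMDISP is ambiguous between
a niche shift and a dispersion difference; a non-significant PERMANOVA
with a strongly significant PERMDISP indicates the invading population
occupies a *narrower part* of the native environmental space rather than
a diverged niche.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridio import OccurrenceSet, Raster2D
from .stats_core import PermutationTestResult


@dataclass
class PCAResult:
    scores: np.ndarray          # (n, k) component scores
    explained: np.ndarray       # (k,) explained-variance fractions, non-increasing
    loadings: np.ndarray        # (p, k) predictor loadings


@dataclass
class DivergenceResult:
    pca: PCAResult
    groups: np.ndarray
    permanova: PermutationTestResult
    permdisp: PermutationTestResult

    def to_dict(self) -> dict:
        return {
            "explained_variance_fractions": [float(x) for x in self.pca.explained],
            "explained_first_two_pct": float(100 * self.pca.explained[:2].sum()),
            "permanova_pseudo_f": self.permanova.statistic,
            "permanova_p": self.permanova.p_value,
            "permdisp_f": self.permdisp.statistic,
            "permdisp_p": self.permdisp.p_value,
            "n_per_group": pd.Series(self.groups).value_counts().to_dict(),
        }


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_env_space(env: np.ndarray) -> PCAResult:
    """PCA of the z-scored environmental matrix (rows = presences).

    Z-scoring makes the decomposition one of the predictor correlation
    structure.  Component signs are fixed by making the largest-magnitude
    element of each loading vector positive, so results are reproducible
    across linear-algebra backends.
    """
    env = np.asarray(env, dtype=float)
    if env.ndim != 2 or env.shape[0] < 3 or env.shape[1] < 2:
        raise ValueError("need at least 3 points and 2 predictors")
    sd = env.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant predictor column; remove it before PCA")
    z = (env - env.mean(axis=0)) / sd
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    explained = s**2 / np.sum(s**2)
    loadings = vt.T
    scores = z @ loadings
    # deterministic sign convention
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(scores=scores, explained=explained, loadings=loadings)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _group_codes(groups) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 points")
    return labels, codes


def pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Distance-based pseudo-F from a squared-distance matrix and labels."""
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    if ss_w == 0:
        return np.inf
    return ((ss_t - ss_w) / (n_groups - 1)) / (ss_w / (n - n_groups))


def _batch_pseudo_f(d2: np.ndarray, code_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for many label vectors at once (rows of ``code_matrix``)."""
    n = d2.shape[0]
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = np.zeros(code_matrix.shape[0])
    for g in range(n_groups):
        z = (code_matrix == g).astype(float)
        ng = z.sum(axis=1)
        quad = np.einsum("pi,ij,pj->p", z, d2, z)  # includes zero diagonal
        ss_w += quad / (2.0 * ng)
    num = (ss_t - ss_w) / (n_groups - 1)
    den = ss_w / (n - n_groups)
    with np.errstate(divide="ignore"):
        return np.where(den == 0, np.inf, num / den)


def permanova(scores, groups, n_perm: int = 9999, seed: int | None = 0,
              exhaustive: bool = False) -> PermutationTestResult:
    """Distance-based permutational MANOVA on Euclidean distances.

    ``exhaustive=True`` enumerates every distinct assignment of the
    observed group sizes (feasible only for tiny samples) and reports the
    exact p as the fraction of assignments with F >= observed, the
    identity included.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    _, codes = _group_codes(groups)
    n_groups = codes.max() + 1
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    observed = pseudo_f(d2, codes, n_groups)

    n = x.shape[0]
    if exhaustive:
        perms = np.array(sorted(set(itertools.permutations(codes))), dtype=int)
        stats = _batch_pseudo_f(d2, perms, n_groups)
        p = float(np.mean(stats >= observed - 1e-12))
        return PermutationTestResult(statistic=float(observed), n_perm=len(perms),
                                     p_value=p, seed=None, name="permanova")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    stats = _batch_pseudo_f(d2, perms, n_groups)
    p = (1 + int(np.sum(stats >= observed - 1e-12))) / (n_perm + 1)
    return PermutationTestResult(statistic=float(observed), n_perm=n_perm,
                                 p_value=float(p), seed=seed, name="permanova")


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _dispersion_f(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on distances to group centroids."""
    dists = np.empty(x.shape[0])
    for g in range(n_groups):
        idx = codes == g
        centroid = x[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(x[idx] - centroid, axis=1)
    grand = dists.mean()
    ss_b = sum((codes == g).sum() * (dists[codes == g].mean() - grand) ** 2
               for g in range(n_groups))
    ss_w = sum(((dists[codes == g] - dists[codes == g].mean()) ** 2).sum()
               for g in range(n_groups))
    n = x.shape[0]
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))


def permdisp(scores, groups, n_perm: int = 9999, seed: int | None = 0) -> PermutationTestResult:
    """Permutational test of multivariate dispersion homogeneity.

    Group centroids and the distances to them are recomputed under each
    permutation of the group labels.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    _, codes = _group_codes(groups)
    n_groups = codes.max() + 1
    observed = _dispersion_f(x, codes, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _dispersion_f(x, rng.permutation(codes), n_groups) >= observed - 1e-12
    p = (1 + count) / (n_perm + 1)
    return PermutationTestResult(statistic=float(observed), n_perm=n_perm,
                                 p_value=float(p), seed=seed, name="permdisp")


# ---------------------------------------------------------------------------
# stage driver
# ---------------------------------------------------------------------------

def extract_presence_env(occ: OccurrenceSet, predictors: list[Raster2D]) -> tuple[np.ndarray, np.ndarray]:
    """Environmental matrix and range labels at presence records.

    Presences falling on missing predictor cells are dropped.
    """
    pres = occ.presences
    cols = [r.value_at(pres["lon"].to_numpy(), pres["lat"].to_numpy()) for r in predictors]
    env = np.column_stack(cols)
    ok = np.isfinite(env).all(axis=1)
    return env[ok], pres["range"].to_numpy()[ok]


def niche_divergence(occ: OccurrenceSet, predictors: list[Raster2D],
                     n_perm: int = 9999, seed: int | None = 0,
                     n_axes: int = 2) -> DivergenceResult:
    """Full divergence stage: PCA, then PERMANOVA and PERMDISP on the
    first ``n_axes`` component scores with range labels as groups."""
    env, groups = extract_presence_env(occ, predictors)
    pca = pca_env_space(env)
    sc = pca.scores[:, :n_axes]
    return DivergenceResult(
        pca=pca,
        groups=groups,
        permanova=permanova(sc, groups, n_perm=n_perm, seed=seed),
        permdisp=permdisp(sc, groups, n_perm=n_perm, seed=seed),
    )
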