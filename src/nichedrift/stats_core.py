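"""Accuracy and permutation statistics used throughout the pipeline.

The statistics here are implemented in-package because their exact
conventions matter downstream: the True Skill Statistic and its
threshold search define model accuracy and the binary reclassification;
Spearman correlation drives the predictor-collinearity filter;
Kruskal-Wallis drives the transferability selection; and the Mantel test
compares (possibly asymmetric) connectivity matrices.  Permutation
p-values use the add-one rule

    p = (1 + #{permuted statistic >= observed}) / (n_perm + 1)

so a reported p is never zero and is bounded below by 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion-matrix summary of a binary prediction at a threshold."""

    sensitivity: float
    specificity: float
    tss: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    n_perm: int
    p_value: float
    seed: int | None = None
    name: str = ""


# ---------------------------------------------------------------------------
# TSS
# ---------------------------------------------------------------------------

def _check_binary_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("labels contain a single class; sensitivity or specificity undefined")


def tss_at_threshold(scores, labels, threshold: float) -> EvaluationResult:
    """True Skill Statistic of ``score >= threshold`` against 0/1 labels.

    TSS = sensitivity + specificity - 1 ranges from -1 to 1; it is
    prevalence-insensitive, unlike overall accuracy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    _check_binary_labels(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvaluationResult(sens, spec, sens + spec - 1.0, float(threshold), tp, fp, tn, fn)


def best_threshold_max_sens_plus_spec(scores, labels) -> tuple[float, EvaluationResult]:
    """Threshold (among observed scores, plus a +inf sentinel) maximising
    sensitivity + specificity; ties resolve to the lowest such threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary_labels(labels)
    candidates = np.unique(scores)
    best: EvaluationResult | None = None
    for thr in candidates:  # unique() is sorted, so ties keep the lowest
        res = tss_at_threshold(scores, labels, thr)
        if best is None or res.tss > best.tss:
            best = res
    sentinel = tss_at_threshold(scores, labels, np.inf)
    if sentinel.tss > best.tss:
        best = sentinel
    return best.threshold, best


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def kruskal_wallis(groups) -> PermutationTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.ptp(pooled) == 0:
        return PermutationTestResult(statistic=0.0, n_perm=0, p_value=1.0, name="kruskal-wallis")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    h /= correction
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return PermutationTestResult(statistic=float(h), n_perm=0, p_value=p, name="kruskal-wallis")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _offdiag(m: np.ndarray) -> np.ndarray:
    """All off-diagonal entries, row-major order."""
    mask = ~np.eye(m.shape[0], dtype=bool)
    return m[mask]


def mantel_test(d1, d2, n_perm: int = 9999, seed: int | None = 0) -> PermutationTestResult:
    """Mantel correlation between two square matrices.

    The statistic is the Pearson correlation over *all* off-diagonal
    entries, so directed (asymmetric) connectivity matrices are compared
    cell-by-cell; symmetric distance matrices reduce to the classical
    Mantel r.  The null permutes one random relabelling simultaneously
    over the rows and columns of ``d2``.  Two-sided interpretation is not
    taken: the test is one-sided toward large positive correlation, the
    relevant alternative for connectivity resemblance.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = d1.shape[0]
    v1 = _offdiag(d1)
    if np.ptp(v1) == 0 or np.ptp(_offdiag(d2)) == 0:
        raise ValueError("off-diagonal entries have zero variance")

    def corr_with(perm: np.ndarray) -> float:
        v2 = _offdiag(d2[np.ix_(perm, perm)])
        a = v1 - v1.mean()
        b = v2 - v2.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    observed = corr_with(np.arange(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += corr_with(rng.permutation(n)) >= observed
    p = (1 + count) / (n_perm + 1)
    return PermutationTestResult(statistic=observed, n_perm=n_perm, p_value=float(p),
                                 seed=seed, name="mantel")
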