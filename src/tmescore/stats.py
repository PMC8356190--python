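"""Statistics for evaluating scores as response biomarkers.

Convention throughout: a higher score means "more likely responder"
(positive label 1).  AUC uses midrank tie handling, so it equals the
Mann-Whitney U statistic divided by n_pos * n_neg.  The DeLong method
provides a nonparametric variance/covariance estimate for AUCs computed on
the same samples, enabling a z-test between two correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from ._exceptions import ValidationError


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    estimate: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValidationError(f"p-value out of range: {self.p}")


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class DeLongResult:
    auc1: float
    auc2: float
    var1: float
    var2: float
    cov12: float
    z: float
    p: float
    paired: bool


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    vals = set(np.unique(y).tolist())
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise ValidationError(f"labels must be binary 0/1, got {sorted(vals)}")
    y = y.astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("both classes must be present")
    return y


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and area under it (higher score = positive class).

    The curve comes from the unique score thresholds (with sentinels); the
    AUC is the trapezoidal area under it, which with midrank tie handling
    equals the normalized Mann-Whitney U statistic.
    """
    x = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} scores vs {len(y)} labels")
    fpr, tpr, thr = _sk_roc_curve(y, x, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=auc, n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()))


def _placements(x: np.ndarray, y01: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank AUC plus per-positive and per-negative placement values."""
    pos = x[y01 == 1]
    neg = x[y01 == 0]
    # psi(pos_i, neg_j) = 1 if pos>neg, 0.5 if tie, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)   # one per positive
    v01 = cmp.mean(axis=0)   # one per negative
    return float(cmp.mean()), v10, v01


def delong_test(scores1, scores2, labels, paired: bool = True,
                labels2=None) -> DeLongResult:
    """DeLong comparison of two AUCs.

    ``paired=True`` (default): both scores were measured on the same samples
    (``labels``); the AUC covariance is estimated from the joint placement
    values.  ``paired=False``: the curves come from independent sample sets
    (``labels2`` for the second curve, defaulting to ``labels``) and the
    covariance is 0.
    """
    x1 = np.asarray(scores1, dtype=float)
    x2 = np.asarray(scores2, dtype=float)
    y1 = _as_binary(labels)
    if paired:
        if not (len(x1) == len(x2) == len(y1)):
            raise ValidationError("paired comparison requires equal-length inputs")
        if labels2 is not None and not np.array_equal(np.asarray(labels2), np.asarray(labels)):
            raise ValidationError("paired comparison requires identical labels")
        y2 = y1
    else:
        y2 = _as_binary(labels2) if labels2 is not None else y1
        if len(x2) != len(y2):
            raise ValidationError("scores2/labels2 length mismatch")
    auc1, v10_1, v01_1 = _placements(x1, y1)
    auc2, v10_2, v01_2 = _placements(x2, y2)
    m1, n1 = len(v10_1), len(v01_1)
    m2, n2 = len(v10_2), len(v01_2)

    def _var(v10, v01):
        s10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
        s01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
        return s10 / len(v10) + s01 / len(v01)

    var1 = _var(v10_1, v01_1)
    var2 = _var(v10_2, v01_2)
    if paired:
        s10 = np.cov(v10_1, v10_2, ddof=1)[0, 1] if m1 > 1 else 0.0
        s01 = np.cov(v01_1, v01_2, ddof=1)[0, 1] if n1 > 1 else 0.0
        cov12 = s10 / m1 + s01 / n1
    else:
        cov12 = 0.0
    vdiff = var1 + var2 - 2.0 * cov12
    if vdiff <= 0:
        if auc1 == auc2:
            z, p = 0.0, 1.0
        else:
            z = np.inf if auc1 > auc2 else -np.inf
            p = 0.0
    else:
        z = (auc1 - auc2) / np.sqrt(vdiff)
        p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(auc1=auc1, auc2=auc2, var1=var1, var2=var2, cov12=cov12,
                        z=float(z), p=float(p), paired=paired)


def mann_whitney(x, y, alternative: str = "two-sided",
                 method: str = "auto") -> TestResult:
    """Mann-Whitney U test; exact by enumeration for small tie-free samples
    (n_x + n_y <= 20), otherwise normal approximation with tie and
    continuity correction.  ``method`` forces "exact"/"asymptotic"."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise ValidationError("method must be 'auto', 'exact' or 'asymptotic'")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                      method=f"Mann-Whitney U ({method})", n=(len(x), len(y)))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; all-identical data gives
    H = 0, p = 1 (degenerate case scipy refuses)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    ns = tuple(len(g) for g in groups)
    if sum(ns) < 3:
        raise ValidationError("need total n >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p=1.0, method="Kruskal-Wallis", n=ns)
    h, p = sps.kruskal(*groups)
    return TestResult(statistic=float(h), p=float(p), method="Kruskal-Wallis", n=ns)


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (minimum-likelihood summation rule).

    The estimate is the sample odds ratio, with a 0.5 continuity correction
    applied to every cell when any cell is zero.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise ValidationError("cells must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("all row/column margins must be >= 1")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return TestResult(statistic=float(odds), p=float(min(p, 1.0)),
                      method="Fisher exact (two-sided)",
                      n=tuple(int(v) for v in t.sum(axis=1)), estimate=float(odds))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation; p from the t approximation (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("length mismatch")
    if len(x) < 3:
        raise ValidationError("need length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("zero variance in ranks")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p=float(min(p, 1.0)),
                      method="Spearman", n=(len(x),))
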