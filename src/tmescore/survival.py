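"""Survival analysis: Kaplan-Meier curves, log-rank testing, univariate Cox
regression and maximally-selected survival cutpoints for continuous scores.

The cutpoint selector mirrors the common "optimal cutpoint" practice for
dichotomizing a continuous biomarker: every observed score value whose
induced split (low = score <= c) leaves at least a ``minprop`` fraction of
samples on each side is a candidate, the standardized two-group log-rank
statistic is computed for each, and the candidate maximizing its absolute
value wins (ties -> smallest cutpoint).  Because the selection maximizes a
statistic, no naive p-value is attached; an optional permutation p-value
(seeded) is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from ._exceptions import ConvergenceError, ValidationError
from .stats import TestResult


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the event times.

    All-censored data yields empty arrays (survival identically 1).
    Censoring at an event time is processed after the events at that time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        if self.event_times.size == 0:
            return 1.0
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    ci95: tuple[float, float]
    p: float
    n: int
    n_events: int
    n_iter: int


@dataclass
class CutpointResult:
    cutpoint: float
    max_stat: float           # |standardized log-rank statistic| at the cutpoint
    n_high: int
    n_low: int
    minprop: float
    candidates_evaluated: int
    permutation_p: float | None = None


def _clean(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if len(t) == 0:
        raise ValidationError("empty survival input")
    if len(t) != len(e):
        raise ValidationError("time/event length mismatch")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValidationError("survival times must be positive and finite")
    vals = set(np.unique(e).tolist())
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise ValidationError("event indicator must be 0/1")
    return t, e.astype(int)


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    t, e = _clean(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(dtype=float)
    return KMCurve(event_times=times, survival=surv,
                   at_risk=ev["at_risk"].to_numpy(dtype=int),
                   n_events=ev["observed"].to_numpy(dtype=int))


def _logrank_oe(t: np.ndarray, e: np.ndarray, g: np.ndarray):
    """(O - E, V) for group 1 over the shared risk sets, fully vectorized.

    Inputs must be sorted by ascending time.
    """
    n = len(t)
    g1_total = int(g.sum())
    ev = e == 1
    te = t[ev]
    ge = g[ev].astype(float)
    if te.size == 0:
        return 0.0, 0.0
    uniq, starts = np.unique(te, return_index=True)
    d = np.add.reduceat(np.ones_like(ge), starts)
    d1 = np.add.reduceat(ge, starts)
    idx = np.searchsorted(t, uniq, side="left")
    n_at = n - idx
    csg = np.concatenate([[0.0], np.cumsum(g)])
    n1_at = g1_total - csg[idx]
    frac = n1_at / n_at
    oe = float(d1.sum() - (d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac * (1.0 - frac) * (n_at - d) / (n_at - 1.0)
    v = float(np.nansum(np.where(n_at > 1, v, 0.0)))
    return oe, v


def logrank_z(time, event, group) -> float:
    """Standardized log-rank statistic (O - E)/sqrt(V) for group 1."""
    t, e = _clean(time, event)
    g = np.asarray(group).astype(int)
    if len(g) != len(t):
        raise ValidationError("group length mismatch")
    if g.sum() == 0 or g.sum() == len(g):
        raise ValidationError("both groups must have >= 1 subject")
    order = np.argsort(t, kind="stable")
    oe, v = _logrank_oe(t[order], e[order], g[order])
    return 0.0 if v == 0 else oe / np.sqrt(v)


def logrank_test(time, event, group) -> TestResult:
    """Two-group log-rank (Mantel-Cox) test: chi-square with 1 df."""
    z = logrank_z(time, event, group)
    stat = z * z
    p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    g = np.asarray(group).astype(int)
    return TestResult(statistic=float(stat), p=p, method="log-rank",
                      n=(int((g == 0).sum()), int((g == 1).sum())))


def _cox_derivatives(beta: float, t, e, x, ties: str):
    """Partial log-likelihood, gradient and information at ``beta``.

    Inputs sorted by ascending time.  ``ties`` is "efron" or "breslow".
    """
    w = np.exp(beta * x)
    # suffix (risk-set) sums: index i -> sum over j >= i
    suf0 = np.cumsum(w[::-1])[::-1]
    suf1 = np.cumsum((w * x)[::-1])[::-1]
    suf2 = np.cumsum((w * x * x)[::-1])[::-1]
    ev = e == 1
    te = t[ev]
    uniq, starts = np.unique(te, return_index=True)
    ev_idx = np.flatnonzero(ev)
    loglik = float(beta * x[ev].sum())
    grad = float(x[ev].sum())
    info = 0.0
    counts = np.diff(np.concatenate([starts, [len(te)]]))
    risk_idx = np.searchsorted(t, uniq, side="left")
    for u in range(len(uniq)):
        members = ev_idx[starts[u]:starts[u] + counts[u]]
        d = len(members)
        r = risk_idx[u]
        s0r, s1r, s2r = suf0[r], suf1[r], suf2[r]
        if ties == "breslow" or d == 1:
            frac = np.zeros(d)
        else:
            frac = np.arange(d) / d
        s0d = w[members].sum()
        s1d = (w[members] * x[members]).sum()
        s2d = (w[members] * x[members] ** 2).sum()
        den = s0r - frac * s0d
        num1 = s1r - frac * s1d
        num2 = s2r - frac * s2d
        loglik -= float(np.log(den).sum())
        grad -= float((num1 / den).sum())
        info += float((num2 / den - (num1 / den) ** 2).sum())
    return loglik, grad, info


def cox_univariate(time, event, x, ties: str = "efron",
                   tol: float = 1e-9, max_iter: int = 50) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton-Raphson.

    Efron tie handling by default (``ties="breslow"`` for the classic
    approximation).  Convergence when |Delta beta| < 1e-9; monotone
    likelihood (perfect separation) raises :class:`ConvergenceError`.
    """
    t, e = _clean(time, event)
    xv = np.asarray(x, dtype=float)
    if len(xv) != len(t):
        raise ValidationError("covariate length mismatch")
    if ties not in ("efron", "breslow"):
        raise ValidationError("ties must be 'efron' or 'breslow'")
    if e.sum() < 2:
        raise ValidationError("need at least 2 events")
    if np.unique(xv).size == 1:
        raise ValidationError("covariate is constant")
    order = np.argsort(t, kind="stable")
    t, e, xv = t[order], e[order], xv[order]
    # center for numerical stability; beta is translation-invariant
    xv = xv - xv.mean()
    beta = 0.0
    for it in range(1, max_iter + 1):
        _, grad, info = _cox_derivatives(beta, t, e, xv, ties)
        if info <= 0:
            raise ConvergenceError("non-positive information; degenerate data")
        step = grad / info
        # clamp Newton overshoot; genuine monotone likelihoods still walk out
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) > 30:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation): |beta| diverged")
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")
    _, _, info = _cox_derivatives(beta, t, e, xv, ties)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    return CoxResult(beta=float(beta), hr=float(np.exp(beta)), se=se, ci95=ci,
                     p=p, n=len(t), n_events=int(e.sum()), n_iter=it)


def surv_cutpoint(time, event, score, minprop: float = 0.1,
                  n_permutations: int = 0, seed: int | None = None) -> CutpointResult:
    """Maximally-selected log-rank cutpoint for a continuous score.

    Returns the observed score value c maximizing |log-rank z| of the split
    low = score <= c, subject to min(n_low, n_high)/n >= minprop.  With
    ``n_permutations > 0`` (``seed`` then mandatory) a permutation p-value
    for the maximal statistic is computed.
    """
    t, e = _clean(time, event)
    s = np.asarray(score, dtype=float)
    if len(s) != len(t):
        raise ValidationError("score length mismatch")
    if not (0 < minprop < 0.5):
        raise ValidationError("minprop must be in (0, 0.5)")
    order = np.argsort(t, kind="stable")
    t, e, s = t[order], e[order], s[order]
    n = len(s)

    def _max_stat(scores: np.ndarray):
        uniq = np.unique(scores)
        best_c, best_z = None, -1.0
        evaluated = 0
        for c in uniq:
            n_low = int((scores <= c).sum())
            n_high = n - n_low
            if min(n_low, n_high) < minprop * n or n_high == 0:
                continue
            evaluated += 1
            g = (scores > c).astype(int)  # group 1 = high
            oe, v = _logrank_oe(t, e, g)
            z = abs(oe / np.sqrt(v)) if v > 0 else 0.0
            if z > best_z + 1e-12:  # strict improvement; ties keep smallest c
                best_z, best_c = z, float(c)
        return best_c, best_z, evaluated

    cut, stat, evaluated = _max_stat(s)
    if cut is None:
        raise ValidationError("no admissible cutpoint under the minprop constraint")
    n_low = int((s <= cut).sum())
    perm_p = None
    if n_permutations > 0:
        if seed is None:
            raise ValidationError("permutation p-value requires an explicit seed")
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            sp = rng.permutation(s)
            c_, z_, _ = _max_stat(sp)
            if c_ is not None and z_ >= stat:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return CutpointResult(cutpoint=cut, max_stat=float(stat), n_high=n - n_low,
                          n_low=n_low, minprop=minprop,
                          candidates_evaluated=evaluated, permutation_p=perm_p)
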