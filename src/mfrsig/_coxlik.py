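"""Newton solvers for the Cox partial likelihood.

Two entry points:

* :func:`fit_univariate_batch` — fits one single-covariate Cox model per
  column of a matrix simultaneously (vectorized over genes), which is what
  makes genome-wide univariate screening cheap.
* :func:`fit_cox` — ordinary multivariate fit for the handful of
  covariates visited by stepwise selection.

Both handle tied event times with the Efron approximation (Breslow
optional) and match lifelines' ``CoxPHFitter`` log-likelihoods and
estimates; lifelines remains the reference implementation in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ITER = 60
_TOL = 1e-9
_BETA_CAP = 25.0  # |beta| beyond this signals monotone likelihood


@dataclass(frozen=True)
class _SurvOrder:
    """Precomputed risk-set structure shared by all Newton iterations.

    Patients are sorted by descending time so risk sets are cumulative
    sums; tied times form groups whose risk set ends at ``group_end``.
    """

    order: np.ndarray            # descending-time permutation
    event_rows: np.ndarray       # rows (desc coords) that are events
    single_ends: np.ndarray      # risk-set end row per untied event time
    single_rows: np.ndarray      # the event's own row per untied event time
    tie_ends: list               # risk-set end row per tied event time
    tie_rows: list               # event rows per tied event time
    n: int


def _prepare(durations: np.ndarray, events: np.ndarray) -> _SurvOrder:
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("durations and events must be 1-d and aligned")
    if not e.any():
        raise ValueError("no events observed; Cox partial likelihood undefined")
    # stable mergesort keeps identical inputs byte-reproducible
    order = np.argsort(-t, kind="mergesort")
    td, ed = t[order], e[order]
    n = t.size

    single_ends, single_rows, tie_ends, tie_rows = [], [], [], []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and td[j + 1] == td[i]:
            j += 1
        ev = np.flatnonzero(ed[i : j + 1]) + i
        if ev.size == 1:
            single_ends.append(j)
            single_rows.append(ev[0])
        elif ev.size > 1:
            tie_ends.append(j)
            tie_rows.append(ev)
        i = j + 1
    return _SurvOrder(
        order=order,
        event_rows=np.flatnonzero(ed),
        single_ends=np.asarray(single_ends, dtype=np.int64),
        single_rows=np.asarray(single_rows, dtype=np.int64),
        tie_ends=tie_ends,
        tie_rows=tie_rows,
        n=n,
    )


def null_loglik(durations, events, ties: str = "efron") -> float:
    """Partial log-likelihood of the empty (beta = 0) model."""
    s = _prepare(np.asarray(durations, float), np.asarray(events, bool))
    ll = 0.0
    for end in s.single_ends:
        ll -= np.log(end + 1.0)
    for end, rows in zip(s.tie_ends, s.tie_rows):
        d = rows.size
        n_risk = end + 1.0
        if ties == "efron":
            ll -= sum(np.log(n_risk - l) for l in range(d))
        else:
            ll -= d * np.log(n_risk)
    return float(ll)


def _batch_ll_grad_hess(xd: np.ndarray, beta: np.ndarray, s: _SurvOrder, ties: str):
    """Loglik, score and information per column, at the current betas.

    ``xd`` is the covariate matrix already in descending-time order.
    """
    eta = xd * beta[None, :]
    w = np.exp(eta)
    wx = w * xd
    wxx = wx * xd
    c0 = np.cumsum(w, axis=0)
    c1 = np.cumsum(wx, axis=0)
    c2 = np.cumsum(wxx, axis=0)

    ll = eta[s.event_rows].sum(axis=0)
    grad = xd[s.event_rows].sum(axis=0).astype(float)
    info = np.zeros_like(beta)

    if s.single_ends.size:
        s0 = c0[s.single_ends]
        s1 = c1[s.single_ends]
        s2 = c2[s.single_ends]
        m1 = s1 / s0
        ll -= np.log(s0).sum(axis=0)
        grad -= m1.sum(axis=0)
        info += (s2 / s0 - m1 * m1).sum(axis=0)

    for end, rows in zip(s.tie_ends, s.tie_rows):
        d = rows.size
        s0, s1, s2 = c0[end], c1[end], c2[end]
        d0, d1, d2 = w[rows].sum(axis=0), wx[rows].sum(axis=0), wxx[rows].sum(axis=0)
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            a0 = s0 - f * d0
            a1 = s1 - f * d1
            a2 = s2 - f * d2
            m1 = a1 / a0
            ll -= np.log(a0)
            grad -= m1
            info += a2 / a0 - m1 * m1
    return ll, grad, info


def fit_univariate_batch(x: np.ndarray, durations, events, ties: str = "efron"):
    """Fit an independent single-covariate Cox model per column of ``x``.

    Returns ``(beta, se, loglik, converged)`` arrays of length
    ``x.shape[1]``.  Columns with no variance (or only among the
    non-comparable) are returned with beta 0, se inf, converged False.
    """
    x = np.asarray(x, dtype=float)
    s = _prepare(np.asarray(durations, float), np.asarray(events, bool))
    xd = x[s.order]
    g = x.shape[1]

    beta = np.zeros(g)
    converged = np.zeros(g, dtype=bool)
    estimable = xd.std(axis=0) > 0
    active = estimable.copy()

    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        ll_cur, grad, info = _batch_ll_grad_hess(xd, beta, s, ties)
        for _ in range(_MAX_ITER):
            if not active.any():
                break
            step = np.where(active & (info > 0), grad / info, 0.0)
            # per-gene step-halving keeps each partial likelihood monotone
            scale = np.ones(g)
            for _half in range(30):
                cand = beta + scale * step
                ll_new, grad_new, info_new = _batch_ll_grad_hess(xd, cand, s, ties)
                # tolerance scales with |ll| so float noise near the
                # optimum does not trigger spurious halving
                bad = active & (~np.isfinite(ll_new) | (ll_new < ll_cur - 1e-9 * (1.0 + np.abs(ll_cur))))
                if not bad.any():
                    break
                scale[bad] *= 0.5
            newly = active & (np.abs(step) < 1e-8)
            converged |= newly
            active &= ~newly
            beta, ll_cur, grad, info = cand, ll_new, grad_new, info_new
            runaway = active & (np.abs(beta) > _BETA_CAP)
            active &= ~runaway

        ll, grad, info = _batch_ll_grad_hess(xd, beta, s, ties)
        se = np.where(info > 0, 1.0 / np.sqrt(info), np.inf)
    converged &= estimable
    return beta, se, ll, converged


def fit_cox(x: np.ndarray, durations, events, ties: str = "efron"):
    """Multivariate Cox fit via Newton-Raphson with step-halving.

    Returns ``(beta, cov, loglik, converged)``.  Raises
    ``np.linalg.LinAlgError`` if the information matrix is singular.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    s = _prepare(np.asarray(durations, float), np.asarray(events, bool))
    xd = x[s.order]

    def ll_grad_hess(beta):
        eta = xd @ beta
        w = np.exp(eta)
        wx = xd * w[:, None]
        wxx = xd[:, :, None] * xd[:, None, :] * w[:, None, None]
        c0 = np.cumsum(w)
        c1 = np.cumsum(wx, axis=0)
        c2 = np.cumsum(wxx, axis=0)

        ll = eta[s.event_rows].sum()
        grad = xd[s.event_rows].sum(axis=0).astype(float)
        hess = np.zeros((p, p))

        if s.single_ends.size:
            s0 = c0[s.single_ends]
            s1 = c1[s.single_ends]
            s2 = c2[s.single_ends]
            m1 = s1 / s0[:, None]
            ll -= np.log(s0).sum()
            grad -= m1.sum(axis=0)
            hess += (s2 / s0[:, None, None]).sum(axis=0) - m1.T @ m1

        for end, rows in zip(s.tie_ends, s.tie_rows):
            d = rows.size
            s0, s1, s2 = c0[end], c1[end], c2[end]
            d0 = w[rows].sum()
            d1 = wx[rows].sum(axis=0)
            d2 = wxx[rows].sum(axis=0)
            for l in range(d):
                f = l / d if ties == "efron" else 0.0
                a0 = s0 - f * d0
                a1 = s1 - f * d1
                a2 = s2 - f * d2
                m1 = a1 / a0
                ll -= np.log(a0)
                grad -= m1
                hess += a2 / a0 - np.outer(m1, m1)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = ll_grad_hess(beta)
    converged = False
    for _ in range(_MAX_ITER):
        step = np.linalg.solve(hess, grad)
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = ll_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(scale * step)) < _TOL or np.max(np.abs(grad)) < 1e-7:
            converged = True
            break
        if np.max(np.abs(beta)) > _BETA_CAP:
            break
    cov = np.linalg.inv(hess)
    return beta, cov, float(ll), converged
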