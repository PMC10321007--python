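"""Scalar random-walk state-space primitives.

All models in this package share one latent structure: a scalar state that
evolves as a Gaussian random walk and is observed (possibly several times
per step, possibly not at all) through additive Gaussian noise.  This module
implements the exact filter, fixed-interval (RTS) smoother and backward
sampler for that structure; observations within a step are absorbed
sequentially, which is exact for a static state within the step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FilterResult:
    """Per-step filter output for a scalar random-walk state."""

    m_pred: np.ndarray  # predictive mean before observations of step s
    P_pred: np.ndarray  # predictive variance before observations of step s
    m_filt: np.ndarray  # posterior mean after observations of step s
    P_filt: np.ndarray  # posterior variance after observations of step s
    loglik: float


def _gauss_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def rw_filter(
    obs: list[np.ndarray],
    obs_var: float,
    q: float,
    init_var: float,
    init_mean: float = 0.0,
) -> FilterResult:
    """Kalman filter for a scalar random-walk state.

    Parameters
    ----------
    obs
        One array of observations per step (may be empty for a step with no
        data).  The state at step 0 is a priori ``N(init_mean, init_var)``;
        between steps it gains variance ``q``.
    obs_var
        Observation variance, shared by all observations.
    """
    n = len(obs)
    m_pred = np.empty(n)
    P_pred = np.empty(n)
    m_filt = np.empty(n)
    P_filt = np.empty(n)
    loglik = 0.0
    m, P = init_mean, init_var
    for s in range(n):
        if s > 0:
            P = P + q
        m_pred[s] = m
        P_pred[s] = P
        for y in np.atleast_1d(obs[s]):
            S = P + obs_var
            loglik += _gauss_logpdf(float(y), m, S)
            K = P / S if S > 0 else 0.0
            m = m + K * (float(y) - m)
            P = (1.0 - K) * P
        m_filt[s] = m
        P_filt[s] = P
    return FilterResult(m_pred=m_pred, P_pred=P_pred, m_filt=m_filt, P_filt=P_filt, loglik=loglik)


def rw_filter_dense(
    y: np.ndarray,
    obs_var: float,
    q: float,
    init_var: float,
    init_mean: float = 0.0,
) -> FilterResult:
    """Fast path of :func:`rw_filter` for exactly one observation per step."""
    n = len(y)
    m_pred = np.empty(n)
    P_pred = np.empty(n)
    m_filt = np.empty(n)
    P_filt = np.empty(n)
    loglik = 0.0
    m, P = init_mean, init_var
    for s in range(n):
        if s > 0:
            P += q
        m_pred[s] = m
        P_pred[s] = P
        S = P + obs_var
        resid = y[s] - m
        loglik += -0.5 * (_LOG2PI + np.log(S) + resid * resid / S)
        K = P / S if S > 0 else 0.0
        m += K * resid
        P *= 1.0 - K
        m_filt[s] = m
        P_filt[s] = P
    return FilterResult(m_pred=m_pred, P_pred=P_pred, m_filt=m_filt, P_filt=P_filt, loglik=float(loglik))


def rts_smoother(fr: FilterResult) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-interval smoother means/variances from a :func:`rw_filter` pass."""
    n = len(fr.m_filt)
    m_s = fr.m_filt.copy()
    P_s = fr.P_filt.copy()
    for s in range(n - 2, -1, -1):
        if fr.P_pred[s + 1] > 0:
            C = fr.P_filt[s] / fr.P_pred[s + 1]
        else:
            C = 0.0
        m_s[s] = fr.m_filt[s] + C * (m_s[s + 1] - fr.m_pred[s + 1])
        P_s[s] = fr.P_filt[s] + C * C * (P_s[s + 1] - fr.P_pred[s + 1])
    return m_s, np.maximum(P_s, 0.0)


def backward_sample(fr: FilterResult, q: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one state path from its joint posterior (FFBS)."""
    n = len(fr.m_filt)
    path = np.empty(n)
    path[-1] = rng.normal(fr.m_filt[-1], np.sqrt(max(fr.P_filt[-1], 0.0)))
    for s in range(n - 2, -1, -1):
        Pf = fr.P_filt[s]
        if q <= 0.0:
            # Degenerate random walk: the state cannot move between steps.
            path[s] = path[s + 1]
            continue
        if Pf <= 0.0:
            path[s] = fr.m_filt[s]
            continue
        var = 1.0 / (1.0 / Pf + 1.0 / q)
        mean = var * (fr.m_filt[s] / Pf + path[s + 1] / q)
        path[s] = rng.normal(mean, np.sqrt(var))
    return path
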