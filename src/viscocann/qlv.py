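"""Quasi-linear viscoelasticity with a Prony relaxation kernel.

Following Fung's quasi-linear theory, the time-dependent nominal stress is
the convolution of a reduced relaxation kernel with the rate of the
quasi-elastic ("instantaneous") stress ``P0``::

    P(t) = int_0^t g(t - s) dP0/ds ds,
    g(t) = g0 + sum_i g_i exp(-t / tau_i),      g0 + sum_i g_i = 1.

Splitting P into a long-term elastic part ``g0 P0`` and per-term history
integrals ``h_i`` yields the standard unconditionally-stable recursive
update on a (possibly non-uniform) time grid::

    P^{n+1}   = g0 P0^{n+1} + sum_i h_i^{n+1}
    h_i^{n+1} = exp(-dt/tau_i) h_i^n
                + g_i (1 - exp(-dt/tau_i)) / (dt/tau_i) (P0^{n+1} - P0^n)

which is exact for P0 piecewise linear in time.  ``convolution_oracle``
evaluates the convolution integral directly by trapezoidal quadrature and
serves as an independent cross-check of the recursion in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # numba accelerates the per-step recursions; plain Python works too
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "PronySet",
    "StressHistory",
    "prony_from_raw",
    "prony_kernel",
    "recursive_stress",
    "convolution_oracle",
]

#: Admissible decade ranges of the two relaxation times (seconds).  tau_1
#: covers sub-second to 10 s processes (faster than the loading ramps),
#: tau_2 the 10-1000 s window bracketing the 300 s relaxation holds; the
#: disjoint ranges make the two terms identifiable (tau_1 < tau_2 always).
TAU1_DECADES = (-2.0, 1.0)
TAU2_DECADES = (1.0, 3.0)

#: Upper bound on each sigmoid-mapped Prony weight; keeps g0 > 0 strictly.
WEIGHT_CEILING = 0.95


@dataclass(frozen=True)
class PronySet:
    """Prony kernel parameters ``(g0, (g1, tau1), (g2, tau2), ...)``.

    Weights partition unity, each weight lies in [0, 1], relaxation times
    are positive and strictly increasing.
    """

    g0: float
    terms: tuple[tuple[float, float], ...]

    def __post_init__(self):
        g = np.array([self.g0] + [t[0] for t in self.terms])
        tau = np.array([t[1] for t in self.terms])
        if abs(g.sum() - 1.0) > 1e-10:
            raise ValueError(f"Prony weights must partition unity; sum = {g.sum()!r}")
        if np.any(g < -1e-15) or np.any(g > 1.0 + 1e-15):
            raise ValueError(f"Prony weights must lie in [0, 1]; got {g.tolist()}")
        if np.any(tau <= 0.0):
            raise ValueError(f"relaxation times must be positive; got {tau.tolist()}")
        if np.any(np.diff(tau) <= 0.0):
            raise ValueError(f"relaxation times must increase; got {tau.tolist()}")

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def weights(self) -> np.ndarray:
        return np.array([t[0] for t in self.terms])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t[1] for t in self.terms])

    @property
    def v(self) -> np.ndarray:
        """Flat parameter vector (g0, g1, tau1, g2, tau2, ...)."""
        return np.concatenate([[self.g0], np.ravel(self.terms)])


@dataclass(frozen=True)
class StressHistory:
    """Time-stamped quasi-elastic and viscoelastic stress series (kPa)."""

    t: np.ndarray
    P0: np.ndarray
    P: np.ndarray
    h: np.ndarray = field(default=None)  # (p, n) per-term history integrals


def prony_from_raw(raw) -> PronySet:
    """Map raw sigmoid outputs ``(s1, s2, s3, s4) in (0,1)`` to a valid PronySet.

    ``g1 = 0.95 s1``; ``g2 = (1 - g1) 0.95 s2``; ``g0 = 1 - g1 - g2`` (strictly
    positive by construction); ``tau1 = 10**(-2 + 3 s3)`` s in [0.01, 10];
    ``tau2 = 10**(1 + 2 s4)`` s in [10, 1000].
    """
    s = np.asarray(raw, dtype=float).ravel()
    if s.shape != (4,):
        raise ValueError(f"expected 4 raw outputs, got shape {s.shape}")
    if np.any(s <= 0.0) or np.any(s >= 1.0):
        raise ValueError(f"raw outputs must lie in the open interval (0, 1); got {s.tolist()}")
    g1 = WEIGHT_CEILING * s[0]
    g2 = (1.0 - g1) * WEIGHT_CEILING * s[1]
    g0 = 1.0 - g1 - g2
    tau1 = 10.0 ** (TAU1_DECADES[0] + (TAU1_DECADES[1] - TAU1_DECADES[0]) * s[2])
    tau2 = 10.0 ** (TAU2_DECADES[0] + (TAU2_DECADES[1] - TAU2_DECADES[0]) * s[3])
    return PronySet(g0=g0, terms=((g1, tau1), (g2, tau2)))


def prony_raw_jacobian(raw) -> np.ndarray:
    """d(g1, g2, tau1, tau2) / d(s1, s2, s3, s4) of the constraint mapping."""
    s = np.asarray(raw, dtype=float).ravel()
    c = WEIGHT_CEILING
    g1 = c * s[0]
    tau1 = 10.0 ** (TAU1_DECADES[0] + (TAU1_DECADES[1] - TAU1_DECADES[0]) * s[2])
    tau2 = 10.0 ** (TAU2_DECADES[0] + (TAU2_DECADES[1] - TAU2_DECADES[0]) * s[3])
    ln10 = np.log(10.0)
    jac = np.zeros((4, 4))
    jac[0, 0] = c
    jac[1, 0] = -c * c * s[1]
    jac[1, 1] = (1.0 - g1) * c
    jac[2, 2] = tau1 * (TAU1_DECADES[1] - TAU1_DECADES[0]) * ln10
    jac[3, 3] = tau2 * (TAU2_DECADES[1] - TAU2_DECADES[0]) * ln10
    return jac


def prony_kernel(pset: PronySet, t):
    """Reduced relaxation kernel g(t); g(0) = 1, g(inf) -> g0, non-increasing."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("kernel time must be non-negative")
    g = np.full(t.shape, pset.g0, dtype=float)
    for gi, taui in pset.terms:
        g += gi * np.exp(-t / taui)
    return g


def _check_times(t: np.ndarray) -> None:
    dt = np.diff(t)
    if np.any(dt <= 0.0):
        idx = int(np.argmax(dt <= 0.0)) + 1
        raise ValueError(
            f"time stamps must be strictly increasing; violation at index {idx} "
            f"(t[{idx - 1}]={t[idx - 1]!r}, t[{idx}]={t[idx]!r})"
        )


def _step_coefficients(dt: np.ndarray, tau: float):
    """Per-step decay exp(-dt/tau) and ramp factor (1-exp(-dt/tau))/(dt/tau).

    The ramp factor is evaluated through expm1 so the dt/tau -> 0 limit
    (value 1) is reached without 0/0; below 1e-8 the series 1 - x/2 is
    exact to double precision.
    """
    x = dt / tau
    e = np.exp(-x)
    em1 = -np.expm1(-x)  # 1 - e, accurately
    kappa = np.where(x < 1e-8, 1.0 - 0.5 * x, em1 / np.where(x == 0.0, 1.0, x))
    return e, kappa


@_njit(cache=False)
def _recurse(e, kappa, dP0, g):  # pragma: no cover - exercised via recursive_stress
    p, m = e.shape
    h = np.zeros((p, m + 1))
    for i in range(p):
        hi = 0.0
        for k in range(m):
            hi = e[i, k] * hi + g[i] * kappa[i, k] * dP0[k]
            h[i, k + 1] = hi
    return h


@_njit(cache=False)
def _recurse_sens(e, kappa, de, dkappa, dP0, g):  # pragma: no cover
    p, m = e.shape
    h = np.zeros((p, m + 1))
    S = np.zeros((p, m + 1))
    T = np.zeros((p, m + 1))
    for i in range(p):
        hi = 0.0
        Si = 0.0
        Ti = 0.0
        for k in range(m):
            Ti = e[i, k] * Ti + de[i, k] * hi + g[i] * dkappa[i, k] * dP0[k]
            Si = e[i, k] * Si + kappa[i, k] * dP0[k]
            hi = e[i, k] * hi + g[i] * kappa[i, k] * dP0[k]
            h[i, k + 1] = hi
            S[i, k + 1] = Si
            T[i, k + 1] = Ti
    return h, S, T


@_njit(cache=False)
def _adjoint(e, kappa, g, rbar):  # pragma: no cover
    p, m = e.shape
    n = m + 1
    out = np.zeros(n)
    for i in range(p):
        hbar = 0.0
        for k in range(n - 1, 0, -1):
            if k < n - 1:
                hbar = rbar[k] + e[i, k] * hbar
            else:
                hbar = rbar[k]
            c = g[i] * kappa[i, k - 1] * hbar
            out[k] += c
            out[k - 1] -= c
    return out


def _coefficient_matrix(dt, taus):
    e = np.empty((len(taus), dt.size))
    kappa = np.empty_like(e)
    for i, tau in enumerate(taus):
        e[i], kappa[i] = _step_coefficients(dt, tau)
    return e, kappa


def recursive_stress(t, P0, pset: PronySet, *, h0=None) -> StressHistory:
    """Viscoelastic stress by the two-line recursive update.

    By default the first sample defines the reference state: all history
    integrals start at zero, so ``P[0] = g0 * P0[0]`` (protocols start
    unloaded with ``P0[0] = 0``).  Each recorded protocol therefore
    restarts its history; to chain protocols instead, pass the previous
    run's final per-term history integrals as ``h0`` (shape ``(p,)``).
    """
    t = np.asarray(t, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    if t.shape != P0.shape:
        raise ValueError(f"time and stress series differ in length: {t.shape} vs {P0.shape}")
    _check_times(t)
    g = pset.weights
    e, kappa = _coefficient_matrix(np.diff(t), pset.taus)
    h = _recurse(e, kappa, np.diff(P0), g)
    if h0 is not None:
        h0 = np.asarray(h0, dtype=float)
        if h0.shape != (pset.p,):
            raise ValueError(f"h0 must have shape ({pset.p},), got {h0.shape}")
        # carried-over history decays with its own exponential from t[0]
        decay = np.exp(-(t[None, 1:] - t[0]) / pset.taus[:, None])
        h[:, 0] += h0
        h[:, 1:] += h0[:, None] * decay
    P = pset.g0 * P0 + h.sum(axis=0)
    return StressHistory(t=t, P0=P0, P=P, h=h)


def recursive_sensitivities(t, P0, g1, g2, tau1, tau2):
    """Recursion output plus exact parameter/input derivatives for training.

    Returns ``(P, dP_dtheta, backprop)`` where ``dP_dtheta`` is the (n, 4)
    array of forward sensitivities of P w.r.t. ``(g1, g2, tau1, tau2)``
    (with ``g0 = 1 - g1 - g2`` implied) and ``backprop(rbar)`` maps an
    adjoint of P onto the adjoint of the quasi-elastic series P0.
    """
    t = np.asarray(t, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    _check_times(t)
    n = t.size
    g0 = 1.0 - g1 - g2
    g = np.array([g1, g2])
    taus = np.array([tau1, tau2])
    dt = np.diff(t)
    dP0 = np.diff(P0)

    e, kappa = _coefficient_matrix(dt, taus)
    de = np.empty_like(e)
    dkappa = np.empty_like(e)
    for i, tau in enumerate(taus):
        de[i] = e[i] * dt / tau**2  # d exp(-dt/tau) / d tau
        dkappa[i] = -np.expm1(-dt / tau) / dt - e[i] / tau
    h, S, T = _recurse_sens(e, kappa, de, dkappa, dP0, g)

    P = g0 * P0 + h.sum(axis=0)
    dP = np.empty((n, 4))
    dP[:, 0] = -P0 + S[0]
    dP[:, 1] = -P0 + S[1]
    dP[:, 2] = T[0]
    dP[:, 3] = T[1]

    def backprop(rbar):
        """Adjoint of P -> adjoint of P0 through the recursion."""
        rbar = np.asarray(rbar, dtype=float)
        return g0 * rbar + _adjoint(e, kappa, g, rbar)

    return P, dP, backprop


def convolution_oracle(t, P0, pset: PronySet) -> StressHistory:
    """Direct trapezoidal quadrature of the convolution integral.

    Numerically integrates ``int_0^t g(t-s) dP0(s)`` in Stieltjes form:
    over each grid interval the stress increment is exact and the kernel
    is averaged between the endpoints (trapezoidal rule), so the only
    error source is the kernel's curvature -- second order in the step,
    uniformly, including at slope discontinuities of P0.  Intended as an
    independent cross-check of ``recursive_stress``, not for production
    use (O(n^2) work).
    """
    t = np.asarray(t, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    if t.shape != P0.shape:
        raise ValueError(f"time and stress series differ in length: {t.shape} vs {P0.shape}")
    _check_times(t)
    n = t.size
    dP0 = np.diff(P0)
    P = np.zeros(n)
    P[0] = pset.g0 * P0[0]
    for k in range(1, n):
        g_left = prony_kernel(pset, t[k] - t[:k])
        g_right = prony_kernel(pset, t[k] - t[1 : k + 1])
        P[k] = np.sum(0.5 * (g_left + g_right) * dP0[:k]) + pset.g0 * P0[0]
    return StressHistory(t=t, P0=P0, P=P)
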