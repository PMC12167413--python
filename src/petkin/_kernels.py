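"""Numerical kernels: exact convolution of an exponential with a
piecewise-linear input.

For an input u(t) given by samples on a (possibly non-uniform) grid and
interpolated linearly, both

    y(t) = int_0^t u(s) * exp(-k (t - s)) ds          (the convolution)
    z(t) = int_0^t y(s) ds                            (its running integral)

have closed forms on each segment.  With h = k*dt and the phi functions

    phi1(h) = (1 - e^-h) / h
    phi2(h) = (1 - phi1) / h
    phi3(h) = (1/2 - phi2) / h

the updates over a segment [t_i, t_i+1] with u(s) = c + m (s - t_i) are

    y_{i+1} = y_i e^-h + dt (c phi1 + m dt phi2)
    z_{i+1} = z_i + dt y_i phi1 + dt^2 (c phi2 + m dt phi3)

The phi functions are evaluated by series for small h to avoid
cancellation; the recurrences are exact otherwise (no quadrature error),
which is what lets the model prediction serve as an oracle against an
independent ODE integration.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _phi123(h: float) -> tuple[float, float, float]:
    if h < 1e-3:
        h2 = h * h
        phi1 = 1.0 - h / 2.0 + h2 / 6.0 - h2 * h / 24.0 + h2 * h2 / 120.0
        phi2 = 0.5 - h / 6.0 + h2 / 24.0 - h2 * h / 120.0 + h2 * h2 / 720.0
        phi3 = 1.0 / 6.0 - h / 24.0 + h2 / 120.0 - h2 * h / 720.0 + h2 * h2 / 5040.0
    else:
        e = np.exp(-h)
        phi1 = (1.0 - e) / h
        phi2 = (1.0 - phi1) / h
        phi3 = (0.5 - phi2) / h
    return phi1, phi2, phi3


@njit(cache=True)
def exp_conv(t: np.ndarray, u: np.ndarray, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (y, z): convolution of u with exp(-k t) and its integral.

    ``t`` strictly increasing, ``u`` sampled on ``t`` (piecewise-linear
    between samples), ``k >= 0`` in inverse time units of ``t``.
    """
    n = t.shape[0]
    y = np.zeros(n)
    z = np.zeros(n)
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        h = k * dt
        c = u[i]
        m = (u[i + 1] - u[i]) / dt
        phi1, phi2, phi3 = _phi123(h)
        e = np.exp(-h)
        y[i + 1] = y[i] * e + dt * (c * phi1 + m * dt * phi2)
        z[i + 1] = z[i] + dt * y[i] * phi1 + dt * dt * (c * phi2 + m * dt * phi3)
    return y, z


@njit(cache=True)
def cumtrapz_grid(t: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-linear sampled curve (exact)."""
    n = t.shape[0]
    z = np.zeros(n)
    for i in range(n - 1):
        z[i + 1] = z[i] + 0.5 * (u[i] + u[i + 1]) * (t[i + 1] - t[i])
    return z
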