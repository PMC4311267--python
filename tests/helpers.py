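"""Shared computation helpers for the test suite."""

import numpy as np

from qssareduce import fixtures, integrate, reduce_once


def tikhonov_reduction_error(eps: float, order: int, t_end: float = 3.0):
    """Max deviation of the slow variable x from its QSSA reduction.

    The toy system dx/dt = -z, eps*dz/dt = x - z is linear, so the full
    solution can be started exactly on its slow eigenvector (no initial
    layer) and the deviation from the reduced model isolates the reduction
    error: O(eps) at order 0 and O(eps^2) at order 1.
    """
    toy = fixtures.build_toy_tikhonov(eps)
    A = np.array([[0.0, -1.0], [1.0 / eps, -1.0 / eps]])
    evals, evecs = np.linalg.eig(A)
    slow = np.argmax(evals.real)
    vec = evecs[:, slow].real
    vec = vec / vec[0]                      # normalise to x0 = 1
    grid = np.arange(0.0, t_end + 1e-9, 0.01)

    full = integrate(toy, {"x": float(vec[0]), "z": float(vec[1])}, None,
                     t_end, step=0.01, rtol=1e-11, atol=1e-14)
    red = reduce_once(toy, "z", order)
    approx = integrate(red, {"x": 1.0}, None, t_end, step=0.01,
                       rtol=1e-11, atol=1e-14)
    n = min(len(full.times), len(approx.times), len(grid))
    return float(np.max(np.abs(full.series("x")[:n] - approx.series("x")[:n])))


def loglog_slope(xs, ys):
    """Least-squares slope of log(y) against log(x)."""
    return float(np.polyfit(np.log(xs), np.log(ys), 1)[0])
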