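"""Independent reference implementations used only by the tests.

These deliberately avoid the library's own code paths: a fixed-step
classical RK4 integrator for the batch ODE and a per-neuron scalar-loop
forward pass for the MLP.
"""

from __future__ import annotations

import math

import numpy as np

from biohybrid.kinetics import SpeciesState, rate_triolein


def rk4_batch(conditions, params, closure, t_grid, n_substeps: int = 200):
    """Classical fixed-step RK4 for dT/dt with algebraic co-species.

    Integrates with ``n_substeps`` uniform steps inside every grid
    interval and returns the T values at the grid points.
    """
    T0 = conditions.T0

    def f(t, T):
        T = min(max(T, 0.0), T0)
        Et, EO, P = (max(v, 0.0) for v in closure(T)[:3])
        r = rate_triolein(SpeciesState(T, Et, EO, P, t), params, conditions.e0)
        if (T <= 0.0 and r < 0.0) or (T >= T0 and r > 0.0):
            return 0.0
        return r

    out = [T0]
    T = T0
    for a, b in zip(t_grid[:-1], t_grid[1:]):
        h = (b - a) / n_substeps
        t = a
        for _ in range(n_substeps):
            k1 = f(t, T)
            k2 = f(t + h / 2, T + h * k1 / 2)
            k3 = f(t + h / 2, T + h * k2 / 2)
            k4 = f(t + h, T + h * k3)
            T = T + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            T = min(max(T, 0.0), T0)
            t += h
        out.append(T)
    return np.array(out)


def loop_forward(weights, biases, x):
    """Scalar per-neuron forward pass (tanh hidden, linear output)."""
    a = list(x)
    last = len(weights) - 1
    for l, (W, b) in enumerate(zip(weights, biases)):
        z = []
        for i in range(W.shape[0]):
            s = b[i]
            for j in range(W.shape[1]):
                s += W[i, j] * a[j]
            z.append(s if l == last else math.tanh(s))
        a = z
    return a[0]
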