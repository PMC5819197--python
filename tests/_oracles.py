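"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own integration / ranking code paths:
a fixed-step classical RK4 integrator and an exhaustive pair-counting AUC.
"""

from __future__ import annotations

import numpy as np


def rk4_integrate(rhs, y0, params, horizon: int = 40, dt: float = 1e-3) -> np.ndarray:
    """Classical fixed-step RK4; returns states sampled at days 1..horizon.

    Output shape (n_states, horizon).
    """
    steps_per_day = int(round(1.0 / dt))
    y = np.asarray(y0, dtype=float).copy()
    out = np.empty((y.size, horizon))
    t = 0.0
    for day in range(1, horizon + 1):
        for i in range(steps_per_day):
            k1 = rhs(t, y, params)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1, params)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2, params)
            k4 = rhs(t + dt, y + dt * k3, params)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        out[:, day - 1] = y
    return out


def auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by exhaustive concordant-pair counting, ties counted 1/2."""
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))
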