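"""Kinetic-model plug-in contract and trajectory simulation.

A wound-healing kinetic model is supplied to the pipeline as a
:class:`KineticModelSpec`: named states, named positive parameters, an
initial state, a right-hand-side function, and a role map that tells the
downstream analysis which state is collagen, which is the fibroblast pool,
and which protein states are screened as biomarker candidates.

The contract is ODE-only.  A delay-differential model would attach its
delayed-state lookup inside ``rhs`` (the signature deliberately passes ``t``
so a plug-in can close over its own history interpolant); the integrator
shipped here does not manage delay state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticModelSpec",
    "Trajectory",
    "SimulationError",
    "rhs_eval",
    "simulate",
    "pathological_scenario",
]

#: values in (-NEGATIVE_CLAMP, 0) produced by integrator noise are set to 0;
#: anything more negative is treated as a genuine model/integration defect.
NEGATIVE_CLAMP = 1e-9


class SimulationError(RuntimeError):
    """Raised when the integrator fails or produces invalid output."""


@dataclass(frozen=True)
class KineticModelSpec:
    """Plug-in contract for an injury-initiated kinetic wound model.

    Parameters
    ----------
    state_names
        Ordered state identifiers.
    param_names
        Ordered parameter identifiers.
    default_params
        Strictly positive defaults, one per parameter (per-day rates,
        dimensionless saturation constants, arbitrary concentration units).
    initial_state
        Non-negative initial value per state (the injured-tissue state at
        t = 0; stored separately from the daily trajectory and never
        screened).
    rhs
        ``rhs(t, state, params) -> dstate/dt``; must return a vector of the
        same length as ``state``.
    marker_roles
        Mapping with keys ``"collagen"`` (one state name), ``"fibroblast"``
        (one state name) and ``"screened"`` (protein states, excluding
        collagen).
    scenario_params
        Names of the fibroblast-apoptosis and collagen-production-rate
        parameters, used by :func:`pathological_scenario`.
    """

    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    default_params: np.ndarray
    initial_state: np.ndarray
    rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    marker_roles: Mapping[str, object]
    scenario_params: Mapping[str, str] = field(
        default_factory=lambda: {
            "fibroblast_apoptosis": "aF",
            "collagen_production": "pC",
        }
    )
    name: str = "kinetic-model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "param_names", tuple(self.param_names))
        object.__setattr__(
            self, "default_params", np.asarray(self.default_params, dtype=float)
        )
        object.__setattr__(
            self, "initial_state", np.asarray(self.initial_state, dtype=float)
        )
        if self.default_params.shape != (len(self.param_names),):
            raise ValueError("default_params length must match param_names")
        if self.initial_state.shape != (len(self.state_names),):
            raise ValueError("initial_state length must match state_names")
        if not np.all(np.isfinite(self.default_params)) or np.any(
            self.default_params <= 0
        ):
            raise ValueError("every default parameter must be strictly positive")
        if not np.all(np.isfinite(self.initial_state)) or np.any(
            self.initial_state < 0
        ):
            raise ValueError("every initial state must be non-negative")
        roles = dict(self.marker_roles)
        for key in ("collagen", "fibroblast", "screened"):
            if key not in roles:
                raise ValueError(f"marker_roles missing role {key!r}")
        states = set(self.state_names)
        if roles["collagen"] not in states:
            raise ValueError("collagen role references an unknown state")
        if roles["fibroblast"] not in states:
            raise ValueError("fibroblast role references an unknown state")
        screened = tuple(roles["screened"])
        unknown = set(screened) - states
        if unknown:
            raise ValueError(f"screened roles reference unknown states: {unknown}")
        if roles["collagen"] in screened:
            raise ValueError("collagen must not be part of the screened set")
        roles["screened"] = screened
        object.__setattr__(self, "marker_roles", roles)

    # -- convenience lookups -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def collagen_state(self) -> str:
        return self.marker_roles["collagen"]

    @property
    def fibroblast_state(self) -> str:
        return self.marker_roles["fibroblast"]

    @property
    def screened_states(self) -> tuple[str, ...]:
        return tuple(self.marker_roles["screened"])

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def params_as_series(self, values: np.ndarray | None = None) -> pd.Series:
        vals = self.default_params if values is None else values
        return pd.Series(np.asarray(vals, dtype=float), index=list(self.param_names))


@dataclass(frozen=True)
class Trajectory:
    """Daily state trajectory on the grid t = 1, 2, ..., horizon days.

    The t = 0 initial state is kept separately (``initial``) and is not part
    of the screened daily grid.
    """

    state_names: tuple[str, ...]
    days: np.ndarray
    values: np.ndarray  # shape (n_states, n_days)
    initial: np.ndarray

    def state(self, name: str) -> np.ndarray:
        return self.values[self.state_names.index(name)]

    def at_day(self, day: int) -> pd.Series:
        j = int(np.where(self.days == day)[0][0])
        return pd.Series(self.values[:, j], index=list(self.state_names))

    def to_frame(self, sim_id: int | str = "reference") -> pd.DataFrame:
        """Tidy export with columns sim_id, day, state, value."""
        n_states, n_days = self.values.shape
        return pd.DataFrame(
            {
                "sim_id": np.repeat(sim_id, n_states * n_days),
                "day": np.tile(self.days, n_states),
                "state": np.repeat(list(self.state_names), n_days),
                "value": self.values.ravel(),
            }
        )


def rhs_eval(
    model: KineticModelSpec,
    t: float,
    state: Sequence[float],
    params: Sequence[float],
) -> np.ndarray:
    """Evaluate the model right-hand side with full contract checking."""
    y = np.asarray(state, dtype=float)
    p = np.asarray(params, dtype=float)
    if y.shape != (model.n_states,):
        raise ValueError(
            f"state has length {y.size}, expected {model.n_states}"
        )
    if p.shape != (model.n_params,):
        raise ValueError(
            f"params has length {p.size}, expected {model.n_params}"
        )
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite state or parameter values")
    dy = np.asarray(model.rhs(t, y, p), dtype=float)
    if dy.shape != y.shape:
        raise ValueError("rhs returned a vector of the wrong length")
    if not np.all(np.isfinite(dy)):
        raise SimulationError("rhs returned non-finite derivatives")
    return dy


def simulate(
    model: KineticModelSpec,
    params: Sequence[float] | None = None,
    horizon: int = 40,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model and sample it on the daily grid 1..horizon.

    Uses adaptive LSODA with relative tolerance ``rtol`` (default 1e-6).
    Small negative values from integrator noise (> -1e-9) are clamped to 0;
    larger negatives, non-finite values or solver failure raise
    :class:`SimulationError`.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1 day")
    p = model.default_params if params is None else np.asarray(params, dtype=float)
    if p.shape != (model.n_params,):
        raise ValueError("parameter vector length mismatch")
    if not np.all(np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("parameters must be finite and strictly positive")
    days = np.arange(1, horizon + 1, dtype=float)
    sol = solve_ivp(
        model.rhs,
        (0.0, float(horizon)),
        model.initial_state,
        method="LSODA",
        t_eval=days,
        args=(p,),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    values = sol.y
    if not np.all(np.isfinite(values)):
        raise SimulationError("integration produced non-finite values")
    if np.any(values <= -NEGATIVE_CLAMP):
        worst = float(values.min())
        raise SimulationError(
            f"trajectory went negative beyond tolerance (min {worst:.3e})"
        )
    values = np.where(values < 0.0, 0.0, values)
    return Trajectory(
        state_names=model.state_names,
        days=days.astype(int),
        values=values,
        initial=model.initial_state.copy(),
    )


def pathological_scenario(
    model: KineticModelSpec, params: Sequence[float] | None = None
) -> np.ndarray:
    """Two-parameter pathological-scarring perturbation.

    Halves the fibroblast apoptosis rate and multiplies the collagen
    production rate by 1.5, leaving every other parameter unchanged.  The
    operation composes (applying it twice quarters the apoptosis rate); it is
    not idempotent.
    """
    p = (model.default_params if params is None else np.asarray(params, dtype=float)).copy()
    if p.shape != (model.n_params,):
        raise ValueError("parameter vector length mismatch")
    try:
        i_apo = model.param_index(model.scenario_params["fibroblast_apoptosis"])
        i_col = model.param_index(model.scenario_params["collagen_production"])
    except (KeyError, ValueError) as exc:
        raise ValueError(
            "model does not map the fibroblast-apoptosis / collagen-production "
            "scenario parameters"
        ) from exc
    p[i_apo] *= 0.5
    p[i_col] *= 1.5
    return p


def with_params(model: KineticModelSpec, params: Sequence[float]) -> KineticModelSpec:
    """Copy of ``model`` with new default parameters."""
    return replace(model, default_params=np.asarray(params, dtype=float))
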