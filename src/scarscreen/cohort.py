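"""Virtual-cohort generation: parameter perturbation and ensemble simulation.

Inter-individual variability is emulated by independently perturbing every
model parameter within a 0.5x-2x band around its default and re-simulating
the full healing time course for each draw.  Sampling is uniform on the
interval by default (log-uniform available), seeded, and reproducible
bit-for-bit from (defaults, n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import KineticModelSpec, SimulationError, Trajectory, simulate

__all__ = ["ParameterDraws", "CohortResult", "sample_parameters", "run_cohort"]

LOWER_FACTOR = 0.5
UPPER_FACTOR = 2.0


@dataclass(frozen=True)
class ParameterDraws:
    """Seeded ensemble of perturbed parameter vectors.

    ``values`` has one row per draw, columns ordered as the model's
    parameters; every entry lies in [default/2, 2*default].
    """

    param_names: tuple[str, ...]
    defaults: np.ndarray
    values: np.ndarray  # (n_draws, n_params)
    seed: int
    distribution: str = "uniform"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def draw_ids(self) -> np.ndarray:
        return np.arange(self.n)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.param_names))
        df.insert(0, "draw_id", self.draw_ids)
        return df


@dataclass
class CohortResult:
    """Reference trajectory plus per-draw trajectories of a virtual cohort.

    ``trajectories`` keeps one stacked array entry per *successful* draw;
    integration failures are recorded in ``failures`` (draw_id -> reason) and
    excluded, never silently dropped: len(success_ids) + len(failures) equals
    the number of draws.
    """

    model_name: str
    reference: Trajectory
    draws: ParameterDraws
    success_ids: np.ndarray
    trajectories: np.ndarray  # (n_success, n_states, n_days)
    failures: dict[int, str] = field(default_factory=dict)
    master_seed: int = 0
    state_names: tuple[str, ...] = ()
    days: np.ndarray = field(default_factory=lambda: np.arange(1, 41))

    @property
    def n_success(self) -> int:
        return len(self.success_ids)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def values_at_day(self, state: str, day: int) -> np.ndarray:
        """Per-draw concentration of ``state`` at ``day`` (successful draws)."""
        j = int(np.where(self.days == day)[0][0])
        return self.trajectories[:, self.state_index(state), j]

    def marker_table(self, states, days) -> pd.DataFrame:
        """Wide table of per-draw concentrations: columns ``<state>_d<day>``."""
        cols = {"draw_id": self.success_ids}
        for day in days:
            for state in states:
                cols[f"{state}_d{day}"] = self.values_at_day(state, day)
        return pd.DataFrame(cols)

    def trajectories_frame(self) -> pd.DataFrame:
        """Tidy per-draw trajectory export: sim_id, day, state, value."""
        n_sim, n_states, n_days = self.trajectories.shape
        return pd.DataFrame(
            {
                "sim_id": np.repeat(self.success_ids, n_states * n_days),
                "day": np.tile(np.tile(self.days, n_states), n_sim),
                "state": np.tile(np.repeat(list(self.state_names), n_days), n_sim),
                "value": self.trajectories.reshape(-1),
            }
        )


def sample_parameters(
    defaults: np.ndarray,
    n: int,
    seed: int,
    param_names=None,
    distribution: str = "uniform",
) -> ParameterDraws:
    """Draw ``n`` perturbed parameter vectors.

    Each parameter is drawn independently on [default/2, 2*default] —
    uniformly by default, or log-uniformly (``distribution="log-uniform"``).
    """
    defaults = np.asarray(defaults, dtype=float)
    if n < 1:
        raise ValueError("n must be at least 1")
    if np.any(defaults <= 0) or not np.all(np.isfinite(defaults)):
        raise ValueError(
            "defaults must be strictly positive (perturbation interval "
            "[default/2, 2*default] is otherwise ill-defined)"
        )
    lo = LOWER_FACTOR * defaults
    hi = UPPER_FACTOR * defaults
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        values = rng.uniform(lo, hi, size=(n, defaults.size))
    elif distribution == "log-uniform":
        values = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, defaults.size)))
    else:
        raise ValueError(f"unknown sampling distribution {distribution!r}")
    names = tuple(param_names) if param_names is not None else tuple(
        f"p{i}" for i in range(defaults.size)
    )
    return ParameterDraws(
        param_names=names,
        defaults=defaults,
        values=values,
        seed=int(seed),
        distribution=distribution,
    )


def run_cohort(
    model: KineticModelSpec,
    draws: ParameterDraws,
    horizon: int = 40,
    master_seed: int = 0,
    on_progress=None,
) -> CohortResult:
    """Simulate every draw plus the unperturbed reference trajectory.

    Failed integrations are captured per draw_id with their reason.  The
    simulation of each draw depends only on its parameter vector, so the
    result is independent of execution order or worker count.
    """
    if draws.n < 1:
        raise ValueError("draws must be non-empty")
    reference = simulate(model, model.default_params, horizon=horizon)
    success_ids: list[int] = []
    failures: dict[int, str] = {}
    trajs: list[np.ndarray] = []
    for i in range(draws.n):
        try:
            tr = simulate(model, draws.values[i], horizon=horizon)
        except (SimulationError, ValueError) as exc:
            failures[i] = str(exc)
            continue
        success_ids.append(i)
        trajs.append(tr.values)
        if on_progress is not None and (i + 1) % 500 == 0:
            on_progress(i + 1, draws.n)
    if draws.n and len(failures) > 0.01 * draws.n:
        import warnings

        warnings.warn(
            f"{len(failures)} of {draws.n} draws failed to integrate "
            "(more than 1%)",
            RuntimeWarning,
            stacklevel=2,
        )
    return CohortResult(
        model_name=model.name,
        reference=reference,
        draws=draws,
        success_ids=np.asarray(success_ids, dtype=int),
        trajectories=(
            np.stack(trajs) if trajs else np.empty((0, model.n_states, horizon))
        ),
        failures=failures,
        master_seed=master_seed,
        state_names=model.state_names,
        days=reference.days,
    )
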