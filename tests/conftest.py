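import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_model():
    from scarscreen import load_reference_model

    return load_reference_model()


@pytest.fixture(scope="session")
def small_cohort(reference_model):
    """A 400-draw seeded cohort for unit-scale checks."""
    from scarscreen import run_cohort, sample_parameters

    draws = sample_parameters(
        reference_model.default_params,
        400,
        seed=11,
        param_names=reference_model.param_names,
    )
    return run_cohort(reference_model, draws, master_seed=11)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    from scarscreen import label_cohort

    return label_cohort(small_cohort)


@pytest.fixture(scope="session")
def demo_report():
    """One full demo-profile pipeline run (shared across acceptance checks)."""
    from scarscreen import demo_config, run_pipeline

    return run_pipeline(demo_config())


def make_cohort(values_by_state, reference_day40, days=(7, 14, 21, 40)):
    """Hand-built CohortResult for distribution-level tests.

    ``values_by_state``: {state: array (n_draws, n_days)} aligned with ``days``;
    ``reference_day40``: {state: scalar} used for every reference day.
    """
    from scarscreen.cohort import CohortResult, ParameterDraws
    from scarscreen.model import Trajectory

    states = tuple(values_by_state)
    days = np.asarray(days, dtype=int)
    n = next(iter(values_by_state.values())).shape[0]
    cube = np.stack([np.asarray(values_by_state[s], dtype=float) for s in states], axis=1)
    ref_values = np.tile(
        np.array([[reference_day40[s]] for s in states], dtype=float), (1, len(days))
    )
    reference = Trajectory(
        state_names=states,
        days=days,
        values=ref_values,
        initial=np.zeros(len(states)),
    )
    draws = ParameterDraws(
        param_names=("p0",),
        defaults=np.ones(1),
        values=np.ones((n, 1)),
        seed=0,
    )
    return CohortResult(
        model_name="synthetic",
        reference=reference,
        draws=draws,
        success_ids=np.arange(n),
        trajectories=cube,
        failures={},
        master_seed=0,
        state_names=states,
        days=days,
    )
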