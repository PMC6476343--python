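import numpy as np
import pytest

from bartsim import CohortSpec, TaskSchedule, fit_mixed_model, generate_cohort


@pytest.fixture(scope="session")
def schedule() -> TaskSchedule:
    return TaskSchedule()


@pytest.fixture(scope="session")
def moderated_fit():
    """One fitted moderation model with a real risk x SCR x BIS interaction.

    Session-scoped: several tests probe the same fit (slopes, JN oracle).
    """
    spec = CohortSpec(
        coefficients={
            "Intercept": 1500.0,
            "risk": -300.0,
            "risk:scr": 1250.0,
            "risk:scr:bis": -25.0,
        }
    )
    table, truth = generate_cohort(spec, seed=42)
    return fit_mixed_model(table), truth


@pytest.fixture(scope="session")
def null_fit():
    """A fitted model from a cohort with no fixed effects beyond the mean."""
    table, truth = generate_cohort(CohortSpec(), seed=11)
    return fit_mixed_model(table), truth
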