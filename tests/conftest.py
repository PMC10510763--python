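import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from drlkit import (
    NoiseModel,
    RateConstants,
    SolutionComposition,
    SpeciesSpec,
)

#: rate constants used throughout: association 5e4 M^-1 s^-1, dissociation 5.4e-4 s^-1
FIG3_RATES = RateConstants(k_on=5.0e4, k_off=5.4e-4)


@pytest.fixture
def fig3_rates() -> RateConstants:
    return FIG3_RATES


@pytest.fixture
def large_excess_comp() -> SolutionComposition:
    """10 uM host pre-equilibrated with 100 equiv ligand, 100 equiv label at t=0."""
    return SolutionComposition.from_equivalents(1e-5, 100, 100)


@pytest.fixture
def default_grid(fig3_rates) -> np.ndarray:
    return np.arange(0.0, 5.0 / fig3_rates.k_off, 1.0)


@pytest.fixture
def ion_pair() -> dict[str, SpeciesSpec]:
    """Light/heavy isotopologue pair at a 5 Da spacing (D5 labelling)."""
    return {
        "bound_unlabelled": SpeciesSpec("M(Py)", 1480.4, formula={"C": 79, "H": 57, "Co": 1, "N": 10, "O": 6}),
        "bound_labelled": SpeciesSpec("M(PyL)", 1485.4, formula={"C": 79, "H": 52, "D": 5, "Co": 1, "N": 10, "O": 6}),
    }


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return NoiseModel.quiet(seed=1)
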