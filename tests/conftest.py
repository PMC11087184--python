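import numpy as np
import pytest

from lvmotion.synthetic import CohortRecipe, PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def recovery_params() -> PhantomParams:
    """Phantom with clean prescribed amplitudes (no twist/translation)."""
    return PhantomParams(radial_amp_endo=6.0, radial_amp_epi=3.0,
                         longitudinal_amp_base=8.0, twist_deg=0.0,
                         translation_amp=(0.0, 0.0), n_phases=25)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic four-group cohort for pipeline-level tests."""
    return generate_cohort(CohortRecipe(n_per_group=3, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def circle(n: int, radius: float = 1.0, center=(0.0, 0.0),
           theta0: float = 0.0) -> np.ndarray:
    t = theta0 + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])
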