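import numpy as np
import pytest

from crmetab import CohortDesign, PhotoperiodSchedule, generate_cohort
from crmetab.respirometry import GasTrace


@pytest.fixture(scope="session")
def schedule():
    return PhotoperiodSchedule()  # lights off 17:00, on 03:00 (14 h light)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noiseless synthetic cohort: every output equals its manifest truth."""
    return generate_cohort(CohortDesign(seed=11, noise_scale=0.0))


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the default measurement-noise level."""
    return generate_cohort(CohortDesign(seed=5))


def make_trace(n=6, fe_o2=0.2000, fe_co2=0.0100, fr_i=30_000.0, mass=0.1, start="2020-01-01T00:00"):
    """Constant-concentration gas trace helper for unit tests."""
    ts = np.datetime64(start) + np.arange(n) * np.timedelta64(10, "m")
    return GasTrace(
        animal_id="t1",
        timestamps=ts,
        fr_i=np.full(n, fr_i),
        fi_o2=np.full(n, 0.2095),
        fe_o2=np.full(n, fe_o2),
        fi_co2=np.full(n, 0.0004),
        fe_co2=np.full(n, fe_co2),
        body_mass=mass,
    )
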