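import pytest

from cloneseed import SimulationConfig, simulate_patient
from cloneseed.pipeline import analyse_patient


SMALL_NOISE_FREE = dict(
    n_clusters=(10, 15),
    n_metastases=(2, 6),
    ccf_noise_sd=0.0,
    fraction_met_to_met=0.6,
)


@pytest.fixture(scope="session")
def noise_free_patient():
    """One deterministic noise-free patient with ground truth."""
    return simulate_patient(SimulationConfig(seed=1, **SMALL_NOISE_FREE))


@pytest.fixture(scope="session")
def analysed_patient(noise_free_patient):
    patient, truth = noise_free_patient
    result = analyse_patient(patient, seed=0, run_signatures=False)
    return patient, truth, result
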