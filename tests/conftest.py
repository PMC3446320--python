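import numpy as np
import pytest

from circasplice import chipmodel, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SimulationConfig(
        n_clusters=6,
        probesets_per_cluster=5,
        probes_per_probeset=4,
        frac_circadian_splice=0.2,
        frac_rhythmic_transcripts=0.5,
        noise_sd=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth.generate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """Purely additive model: no noise, no probe spread, nothing planted."""
    return synth.SimulationConfig(
        n_clusters=4,
        probesets_per_cluster=3,
        probes_per_probeset=4,
        frac_circadian_splice=0.0,
        frac_ultradian_splice=0.0,
        frac_rhythmic_transcripts=0.5,
        probe_affinity_sd=0.0,
        noise_sd=0.0,
        seed=5,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return synth.generate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def small_scores(small_dataset):
    fits, _ = chipmodel.fit_clusters(small_dataset.intensities, small_dataset.layout)
    return chipmodel.firma_scores(fits, small_dataset.layout)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
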