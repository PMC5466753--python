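import numpy as np
import pytest

import ftirlip as fl
from ftirlip.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def experiment():
    """Default full-factorial synthetic experiment (648 raw spectra)."""
    return fl.generate_experiment(seed=1)


@pytest.fixture(scope="session")
def preprocessed(experiment):
    """Averaged + SG-derivative + EMSC spectra of the default experiment."""
    corrected, _ = fl.preprocess_pipeline(experiment.spectra)
    return corrected


@pytest.fixture(scope="session")
def design210():
    """210-biological-sample design (630 raw spectra) via the drop list."""
    return fl.generate_experiment(
        SyntheticConfig(drop_conditions=fl.STUDY_210_DROP, seed=3)
    )


@pytest.fixture(scope="session")
def noise_free():
    """Deterministic experiment: no noise, no scatter, exact compositions."""
    return fl.generate_experiment(SyntheticConfig.noise_free(seed=5))


@pytest.fixture
def small_set():
    """Tiny 3-sample SpectrumSet on the standard 4000..502 step-6 grid."""
    n = int(np.floor((4000 - 500) / 6)) + 1
    grid = 4000.0 - 6.0 * np.arange(n)
    rng = np.random.default_rng(42)
    rows = rng.random((3, n))
    meta = [
        fl.SampleMeta(f"sp_{20}C_d01_b{i}_t1", "sp", 20.0, 1, i, 1)
        for i in (1, 2, 3)
    ]
    return fl.SpectrumSet(grid, rows, meta)
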