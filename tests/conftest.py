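import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def contents():
    """The packaged 44-batch content table (mg/g)."""
    from qmarker import datasets

    return datasets.load_contents()


@pytest.fixture(scope="session")
def default_fingerprint():
    """Synthetic 44-batch, 25-peak fingerprint at the documented default
    configuration, matched into a common-peak matrix (computed once; the
    heaviest shared fixture)."""
    from qmarker import fingerprint as fp
    from qmarker import simulate as sim

    config = sim.SimulationConfig()
    chroms = sim.generate_chromatograms(config)
    tables = {
        b: fp.detect_peaks(c, min_height=2.0, min_prominence=2.0)
        for b, c in chroms.items()
    }
    matrix = fp.match_common_peaks(tables)
    return config, tables, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
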