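import numpy as np
import pandas as pd
import pytest

from aquacarb import ModelConfig, RateMeasurement


@pytest.fixture
def quick_config():
    """Short-chain MCMC settings for tests (same model, scaled down)."""
    return ModelConfig(n_chains=2, n_iter=3000, n_burnin=1000, seed=7)


@pytest.fixture
def tiny_measurements():
    """Six hand-built measurements across two categories."""
    return [
        RateMeasurement("s1", "a", 100.0, 20.0, "reported", ecosystem_category="lake",
                        salinity_class="fresh", inundation_class="permanent"),
        RateMeasurement("s1", "b", 50.0, 5.0, "reported", ecosystem_category="lake",
                        salinity_class="fresh"),
        RateMeasurement("s2", "c", 200.0, ecosystem_category="lake",
                        salinity_class="fresh"),
        RateMeasurement("s3", "d", 80.0, 8.0, "reported", ecosystem_category="mangrove",
                        salinity_class="saline", inundation_class="tidal"),
        RateMeasurement("s3", "e", 60.0, ecosystem_category="mangrove",
                        inundation_class="tidal"),
        RateMeasurement("s4", "f", 40.0, ecosystem_category="mangrove",
                        salinity_class="saline", inundation_class="tidal"),
    ]


@pytest.fixture
def write_csv(tmp_path):
    """Write a list of row dicts to a CSV and return its path."""

    def _write(rows, name="data.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
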