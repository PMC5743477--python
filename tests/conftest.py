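import numpy as np
import pandas as pd
import pytest

from localadapt.design_and_io import TransplantDataset
from localadapt.synthetic_data import generate_dataset, study_design_config


@pytest.fixture(scope="session")
def bench_config():
    """Benchmark design, moderate sympatry advantage, fixed seed."""
    return study_design_config(0.2, seed=11)


@pytest.fixture(scope="session")
def bench_dataset(bench_config):
    return generate_dataset(bench_config)


@pytest.fixture(scope="session")
def null_dataset():
    """Benchmark design with no local adaptation (delta = 0)."""
    return generate_dataset(study_design_config(0.0, seed=23))


@pytest.fixture()
def tiny_frame():
    """Two species, two regions, hand-enterable biomasses."""
    rows = []
    for sp, base in (("a", 1.0), ("b", 10.0)):
        for g in ("N", "S"):
            for e in ("N", "S"):
                for r in (1, 2, 3):
                    rows.append(
                        {
                            "species": sp,
                            "garden": g,
                            "ecotype": e,
                            "replicate": r,
                            "biomass": base + 0.1 * r + 0.5 * (e == g),
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_dataset(tiny_frame):
    return TransplantDataset(tiny_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
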