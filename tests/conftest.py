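import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from halotrans.pipeline import RunConfig, run_all
from halotrans.synthetic_data import SimConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset for fast structural checks."""
    return simulate_dataset(SimConfig(n_genes=120, n_families=8, n_contaminants=6, seed=1))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions (1,000 genes)."""
    return simulate_dataset(SimConfig(seed=5))


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic fixture."""
    data_dir = tmp_path_factory.mktemp("dataset")
    out_dir = tmp_path_factory.mktemp("run")
    write_dataset(default_dataset, data_dir)
    report = run_all(RunConfig(input_dir=str(data_dir), out_dir=str(out_dir), seed=5))
    return default_dataset, report
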