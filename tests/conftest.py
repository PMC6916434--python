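import numpy as np
import pandas as pd
import pytest

from methsig.core_io import ProbeMatrix, SampleSheet
from methsig.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic cohort (seed 7) shared across the suite."""
    return simulate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_cohort(default_study):
    matrix, sheet, _, truth = default_study
    return matrix, sheet, truth


def random_beta_matrix(n_probes=50, n_samples=10, seed=0, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    values = rng.beta(2.0, 2.0, size=(n_probes, n_samples))
    if missing_rate:
        values = np.where(rng.random(values.shape) < missing_rate, np.nan, values)
    probe_ids = [f"cg{i:05d}" for i in range(n_probes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    return ProbeMatrix(probe_ids, sample_ids, values, "beta")


def make_sheet(rows):
    """Sample-sheet helper filling optional columns with defaults."""
    full = []
    for row in rows:
        base = {
            "age": np.nan,
            "location": "distal",
            "batch": "B1",
            "aspirin_user": "unknown",
            "hrt_user": "unknown",
            "pair_id": np.nan,
        }
        base.update(row)
        full.append(base)
    return SampleSheet(pd.DataFrame(full))
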