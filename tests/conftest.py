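import numpy as np
import pandas as pd
import pytest

import lipidiag as ld
from lipidiag.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_study():
    """One full-size simulated study (cohort, peaks, truth) at a fixed seed."""
    return ld.simulate_study(seed=1)


@pytest.fixture(scope="session")
def normalized_study(default_study):
    cohort, peaks, truth = default_study
    normalized, model = ld.normalize(peaks)
    return cohort, normalized, model, truth


@pytest.fixture
def small_config():
    """A scaled-down simulation for fast unit tests (not the study conditions)."""
    return SimulationConfig(
        n_per_group={"CTRL": 20, "AA": 15, "CRC": 20},
        n_features=24,
        n_batches=2,
        qc_interval=6,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_peak_table(study_values: np.ndarray, feature_meta: pd.DataFrame,
                    n_qc: int = 3) -> ld.PeakTable:
    """Hand-built peak table: one batch, leading/trailing QC_CAL injections."""
    n_study = study_values.shape[0]
    ids = [f"S{i:03d}" for i in range(n_study)]
    qc_ids = [f"QC{i}" for i in range(n_qc)]
    roles = ["QC_CAL"] * n_qc + ["STUDY"] * n_study
    qc_vals = np.nanmedian(study_values, axis=0, keepdims=True).repeat(n_qc, axis=0)
    ab = pd.DataFrame(np.vstack([qc_vals, study_values]), index=qc_ids + ids,
                      columns=feature_meta.index)
    samples = pd.DataFrame(
        {"batch_id": "B1", "injection_order": np.arange(1, n_qc + n_study + 1),
         "sample_role": roles},
        index=ab.index,
    )
    return ld.PeakTable(ab, samples, feature_meta)
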