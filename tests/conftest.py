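import numpy as np
import pandas as pd
import pytest

from proteoqc import QuantMatrix, RunMetadata, SimulationConfig


@pytest.fixture
def small_matrix() -> QuantMatrix:
    """3 proteins x 4 runs iBAQ matrix with one missing entry."""
    df = pd.DataFrame(
        {"A_r1": [2.0, 3.0, 5.0],
         "A_r2": [7.0, np.nan, 3.0],
         "B_r1": [1.0, 1.0, 8.0],
         "B_r2": [4.0, 2.0, 4.0]},
        index=["P1", "P2", "P3"])
    return QuantMatrix(df, unit_tag="iBAQ")


@pytest.fixture
def small_metadata() -> RunMetadata:
    return RunMetadata(pd.DataFrame({
        "run_id": ["A_r1", "A_r2", "B_r1", "B_r2"],
        "group_label": ["A", "A", "B", "B"],
        "replicate_index": [1, 2, 1, 2],
        "experiment_id": ["E1"] * 4,
        "injection_index": [1, 2, 3, 4],
        "month": [1] * 4,
    }))


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noise-free, fully detected quartet design for ideal-pipeline checks."""
    return SimulationConfig(
        n_proteins=200, dep_fraction=0.0, specific_fraction=0.0,
        cv_profile={"low": 0.0, "medium": 0.0, "high": 0.0},
        detection_midpoint_log10=-np.inf, drift_heterogeneity=0.0, seed=11)


@pytest.fixture(scope="session")
def default_sim():
    """One realistic simulated quartet experiment shared across tests."""
    from proteoqc import simulate_experiment
    cfg = SimulationConfig(n_proteins=800, seed=42)
    return simulate_experiment(cfg)
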