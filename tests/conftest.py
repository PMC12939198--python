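import numpy as np
import pandas as pd
import pytest

from trmspatial import SimulationConfig, gate_phenotypes, simulate_sample


@pytest.fixture
def small_config():
    """Compact sample: a few hundred cells, enough tumor for region building."""
    return SimulationConfig(
        seed=7,
        n_islets=3,
        islet_sd_um=40.0,
        tumor_per_islet=60.0,
        immune_counts={"naive_trm": 50, "exhausted_trm": 30, "cd8": 40, "other": 40},
    )


@pytest.fixture
def gated_sample(small_config):
    cells, _ = simulate_sample(small_config, 0)
    return gate_phenotypes(cells, small_config.gating_config())


def make_point_table(tumor_xy, target_xy, target_label="naive_trm"):
    """Minimal gated table from raw coordinates, for geometry/statistics tests."""
    tumor_xy = np.asarray(tumor_xy, dtype=float).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    n = len(tumor_xy) + len(target_xy)
    return pd.DataFrame(
        {
            "sample_id": "s0",
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": np.r_[tumor_xy[:, 0], target_xy[:, 0]],
            "y_um": np.r_[tumor_xy[:, 1], target_xy[:, 1]],
            "phenotype": ["tumor"] * len(tumor_xy) + [target_label] * len(target_xy),
        }
    )
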