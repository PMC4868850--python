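import numpy as np
import pandas as pd
import pytest

import agecog as ac


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with planted age and behavior genes."""
    cfg = ac.SimulationConfig(
        n_genes=1200,
        n_age_de=80,
        n_behavior_genes=80,
        age_lfc=1.0,
        behavior_r=0.7,
        seed=11,
    )
    matrix, samples, truth = ac.generate_counts(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture(scope="session")
def normalized(small_dataset):
    _, matrix, samples, _ = small_dataset
    filtered = ac.filter_low_counts(matrix)
    return ac.normalize(filtered), samples


@pytest.fixture()
def toy_counts():
    frame = pd.DataFrame(
        {
            "s1": [10, 0, 3, 100],
            "s2": [20, 0, 6, 200],
            "s3": [15, 0, 4, 150],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ac.CountMatrix(frame)


def aged_submatrix(nm: ac.NormalizedMatrix, samples: pd.DataFrame):
    """Expression restricted to aged animals, plus their TTC scores."""
    aged = samples.loc[samples["age_group"] == "aged"]
    ids = aged["sample_id"].tolist()
    sub = ac.NormalizedMatrix(
        nm.values[ids], nm.size_factors[ids], nm.log_transformed
    )
    return sub, aged.set_index("sample_id")["set_shift_ttc"]
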