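import numpy as np
import pandas as pd
import pytest

import tmeniche as tm


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study configuration shared across tests."""
    return tm.SimConfig(
        seed=7,
        n_patients_per_group=4,
        rois_per_patient=2,
        cells_per_roi=150,
        n_markers=8,
        n_clusters=3,
        planted_pairs=[(0, 1, "groupA", 0.9)],
        n_st_samples_per_group=3,
        st_grid=(20, 20),
        n_genes=120,
        niche_radius=4.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return tm.gen_imc_cohort(small_config)


@pytest.fixture(scope="session")
def small_st(small_config):
    samples, gt = tm.gen_st_cohort(small_config)
    for s in samples:
        tm.normalize_st(s)
    return samples, gt


def make_st_toy(counts, rows, cols, sample_id="toy", group="groupA"):
    """Dense toy STSample from a spots x genes count array on a grid."""
    counts = np.asarray(counts)
    n_spots, n_genes = counts.shape
    assert n_spots == rows * cols
    pos = pd.DataFrame(
        {
            "array_row": np.repeat(np.arange(rows), cols),
            "array_col": np.tile(np.arange(cols), rows),
        },
        index=[f"s{i}" for i in range(n_spots)],
    )
    genes = [f"G{j}" for j in range(n_genes)]
    return tm.make_st_sample(sample_id, group, counts, genes, pos)
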