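import numpy as np
import pandas as pd
import pytest

from tfredist import synthetic_data as syn
from tfredist.io_formats import CountMatrix


@pytest.fixture(scope="session")
def small_landscape():
    """A compact seeded landscape shared by read-only tests."""
    cfg = syn.SimulationConfig(seed=7, n_peaks=400, n_genes=120)
    return syn.simulate_peak_landscape(cfg)


@pytest.fixture()
def two_group_counts():
    """A 2-condition CountMatrix with a known planted log2FC of +2 for a
    minority of features (so median-of-ratios normalization stays anchored
    on the null majority)."""
    n = 100
    lfc = np.zeros((n, 2))
    lfc[:20, 1] = 2.0
    truth = syn.TruthTable.from_planted_lfc(
        [f"f{i}" for i in range(n)], (0, 30), lfc, seed=3
    )
    cfg = syn.SimulationConfig(seed=3, dispersion=0.05)
    return syn.simulate_timecourse_counts(truth, cfg, timepoints=(0, 30)), truth


def make_count_matrix(arr, conditions, timepoints=None, feature_ids=None):
    arr = np.asarray(arr)
    n_feat, n_samp = arr.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    sample_ids = [f"s{j}" for j in range(n_samp)]
    if timepoints is None:
        timepoints = [0 if c == conditions[0] else 30 for c in conditions]
    reps = {}
    rep_idx = []
    for c, t in zip(conditions, timepoints):
        reps[(c, t)] = reps.get((c, t), 0) + 1
        rep_idx.append(reps[(c, t)])
    meta = pd.DataFrame(
        {"condition": conditions, "timepoint": timepoints, "replicate": rep_idx},
        index=sample_ids,
    )
    return CountMatrix(pd.DataFrame(arr, index=feature_ids, columns=sample_ids), meta)
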