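import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from volatax import PeakTable, SampleTable
from volatax.preprocess import DistanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_peak_table(matrix, compounds=None, samples=None, annotations=None):
    matrix = np.asarray(matrix, dtype=float)
    n_c, n_s = matrix.shape
    compounds = compounds or [f"c{i + 1}" for i in range(n_c)]
    samples = samples or [f"s{j + 1}" for j in range(n_s)]
    return PeakTable(
        compound_ids=tuple(compounds),
        sample_ids=tuple(samples),
        abundances=matrix,
        annotations=annotations,
    )


def make_sample_table(sample_ids, replicate_groups, group_labels, **extra):
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "replicate_group": list(replicate_groups),
            "group_label": list(group_labels),
        }
    )
    for col, values in extra.items():
        df[col] = values
    return SampleTable(df)


def euclidean_dm(points, ids=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    n = points.shape[0]
    ids = ids or [f"s{i + 1}" for i in range(n)]
    return DistanceMatrix(
        sample_ids=tuple(ids),
        values=squareform(pdist(points)),
        metric_name="euclidean",
    )


@pytest.fixture
def two_cluster_dm():
    """Two tight clusters 10x further apart than their spread."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.5, size=(5, 3))
    b = rng.normal(0.0, 0.5, size=(5, 3)) + np.array([10.0, 0, 0])
    points = np.vstack([a, b])
    groups = ["A"] * 5 + ["B"] * 5
    return euclidean_dm(points), groups


@pytest.fixture
def small_pt():
    return make_peak_table(
        [[2.0, 4.0, 3.0, 0.0, 0.0, 0.0],
         [0.0, 0.0, 0.0, 5.0, 7.0, 6.0],
         [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]],
        compounds=["alpha", "beta", "gamma"],
        samples=["s1", "s2", "s3", "s4", "s5", "s6"],
    )


@pytest.fixture
def small_st():
    return make_sample_table(
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        ["r1", "r1", "r1", "r2", "r2", "r2"],
        ["A", "A", "A", "B", "B", "B"],
    )
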