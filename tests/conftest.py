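import numpy as np
import pytest

from micropick import FeatureTable, PhenotypeMetadata


@pytest.fixture
def counts_table():
    """3 samples x 2 features of integer counts."""
    return FeatureTable(
        sample_ids=("s1", "s2", "s3"),
        feature_ids=("f1", "f2"),
        values=np.array([[6.0, 2.0], [2.0, 2.0], [1.0, 9.0]]),
        mode="counts",
    )


@pytest.fixture
def two_class_table():
    """4-sample relative table with strict centroid-distance ranks.

    case centroid = (0.3, 0.7), control centroid = (0.75, 0.25);
    Bray-Curtis to the opposite-class centroid:
    A=0.55, B=0.35, C=0.60, D=0.30.
    """
    table = FeatureTable(
        sample_ids=("A", "B", "C", "D"),
        feature_ids=("f1", "f2"),
        values=np.array([[0.2, 0.8], [0.4, 0.6], [0.9, 0.1], [0.6, 0.4]]),
        mode="relative",
    )
    phenotype = PhenotypeMetadata(
        labels={"A": "case", "B": "case", "C": "control", "D": "control"}
    )
    return table, phenotype


def random_relative_table(rng, n_samples, n_features, prefix="s"):
    vals = rng.dirichlet(np.ones(n_features), size=n_samples)
    return FeatureTable(
        sample_ids=tuple(f"{prefix}{i:03d}" for i in range(n_samples)),
        feature_ids=tuple(f"f{j:03d}" for j in range(n_features)),
        values=vals,
        mode="relative",
    )


def random_count_table(rng, n_samples, n_features, high=25):
    vals = rng.integers(0, high, size=(n_samples, n_features)).astype(float)
    vals[vals.sum(axis=1) == 0, 0] = 1.0  # no all-zero samples
    return FeatureTable(
        sample_ids=tuple(f"s{i:03d}" for i in range(n_samples)),
        feature_ids=tuple(f"f{j:03d}" for j in range(n_features)),
        values=vals,
        mode="counts",
    )
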