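import numpy as np
import pytest

from varmkl.variant_data import (
    FeatureGroupSet,
    LabeledDataset,
    Variant,
)


@pytest.fixture
def toy_dataset() -> LabeledDataset:
    """Six labeled variants: 3 pathogenic, 3 control with MAFs."""
    return LabeledDataset.from_variants(
        [
            Variant("chr1", 100, "A", "G", 1, coding=True),
            Variant("chr1", 5000, "C", "T", 1, coding=False),
            Variant("chr2", 250, "G", "A", 1, coding=True),
            Variant("chr1", 900, "T", "C", -1, maf=0.05, coding=False),
            Variant("chr1", 99_000, "A", "C", -1, maf=0.01, coding=True),
            Variant("chr2", 260, "C", "G", -1, maf=0.30, coding=False),
        ]
    )


@pytest.fixture
def toy_features(toy_dataset) -> FeatureGroupSet:
    rng = np.random.default_rng(42)
    n = len(toy_dataset)
    mats = {
        "A": rng.normal(size=(n, 3)),
        "B": rng.normal(size=(n, 2)),
    }
    mats["B"][1] = np.nan  # group-missing row
    return FeatureGroupSet(mats, group_names=["A", "B"])


def separable_problem(seed: int = 0, n: int = 30):
    """Well-separated two-class feature matrix and labels."""
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [rng.normal(2.0, 1.0, size=(half, 4)), rng.normal(-2.0, 1.0, size=(n - half, 4))]
    )
    y = np.r_[np.ones(half), -np.ones(n - half)]
    return x, y
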