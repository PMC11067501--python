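import numpy as np
import pytest

from citegate.core import CellDataset, NormalizationTag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, markers=None, cells=None, **kwargs):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return CellDataset(
        values=values,
        marker_names=markers or [f"M{j}" for j in range(m)],
        cell_ids=cells or [f"c{i}" for i in range(n)],
        **kwargs,
    )


def make_normalized(values, markers=None, cells=None, **kwargs):
    """Dataset tagged as already normalized (values may be negative)."""
    kwargs.setdefault("normalization", NormalizationTag("arcsinh", {"cofactor": 5.0}))
    return make_dataset(values, markers, cells, **kwargs)


@pytest.fixture
def small_raw():
    """3 cells × 2 markers with full metadata."""
    return make_dataset(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        markers=["CD19", "CD27"],
        cells=["a", "b", "c"],
        truth_label=np.array(["naive", "naive", "memory"], dtype=object),
        sample_id=np.array(["s1", "s1", "s2"], dtype=object),
        group=np.array(["g1", "g1", "g2"], dtype=object),
    )
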