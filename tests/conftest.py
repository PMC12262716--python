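import numpy as np
import pytest

from consentropy import SpatialLabeling, build_collection


@pytest.fixture
def make_labeling():
    """Build a SpatialLabeling from a label vector on a default line/grid."""

    def _make(labels, coords=None, ids=None, method="m", config="c", sample=""):
        labels = np.asarray(labels)
        n = len(labels)
        if coords is None:
            coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        if ids is None:
            ids = [f"obs{i:04d}" for i in range(n)]
        return SpatialLabeling(
            observation_ids=np.asarray(ids, dtype=object),
            coords=np.asarray(coords, dtype=float),
            labels=labels,
            method_id=method,
            config_id=config,
            sample_id=sample,
        )

    return _make


@pytest.fixture
def make_collection(make_labeling):
    """Build a LabelingCollection from integer label columns."""

    def _make(columns, coords=None, methods=None):
        columns = [np.asarray(c) for c in columns]
        if methods is None:
            methods = [f"m{j}" for j in range(len(columns))]
        labelings = [
            make_labeling(col, coords=coords, method=meth)
            for col, meth in zip(columns, methods)
        ]
        return build_collection(labelings)

    return _make
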