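import numpy as np
import pytest

from deepchronnect.io import RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_ts(rng):
    """A 3-region, 20-sample random run."""
    return RoiTimeSeries(
        values=rng.standard_normal((20, 3)),
        tr_seconds=0.72,
        node_ids=["a", "b", "c"],
        run_id="r0",
        subject_id="s0",
    )


@pytest.fixture
def five_region_ts(rng):
    """A 5-region, 128-sample random run (surrogate-preservation checks)."""
    return RoiTimeSeries(
        values=rng.standard_normal((128, 5)),
        tr_seconds=0.72,
        node_ids=[f"n{i}" for i in range(5)],
        run_id="r1",
        subject_id="s1",
    )
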