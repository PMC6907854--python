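import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spreadfoci.detect import FocusRecord
from spreadfoci.simulate import NucleusGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def circle_nucleus():
    return NucleusGeometry(nucleus_id="nuc", semi_axes=(1800.0, 1800.0))


def make_records(xy, lengths, channel, nucleus_id="nuc"):
    """Focus records from coordinate/length arrays (test helper)."""
    return [
        FocusRecord(
            nucleus_id=nucleus_id,
            channel=channel,
            focus_id=f"{channel}-{i:04d}",
            x_nm=float(x),
            y_nm=float(y),
            major_length_nm=float(l),
        )
        for i, ((x, y), l) in enumerate(zip(xy, lengths))
    ]


@pytest.fixture
def record_factory():
    return make_records
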