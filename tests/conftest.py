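import numpy as np
import pytest

from chondroview.synth import FieldSpec, IFFieldSpec, ImpactSpec, TraceSimSpec


@pytest.fixture
def small_field():
    """A quick-to-render field used wherever full size is unnecessary."""
    return FieldSpec(width=256, height=256, n_cells=20, seed=11)


@pytest.fixture
def impact_spec(small_field):
    return ImpactSpec(field=small_field, impact_radius=40.0, post_shift=(3, -2))


@pytest.fixture
def trace_spec():
    return TraceSimSpec(n_cells=50, seed=11)


@pytest.fixture
def if_spec():
    return IFFieldSpec(n_cells_humeral=12, n_cells_glenoid=12, width=384, height=384,
                       seed=11)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
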