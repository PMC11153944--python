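import numpy as np
import pytest

from gaintimer import EventOrder, SegmentState


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def order():
    return EventOrder.from_string


@pytest.fixture
def diploid_gain_segment():
    """A clonal 2+1 segment in a pure tumour."""
    return SegmentState(
        chrom="8", start=1, end=10_000_000, states=[(2, 1, 1.0)],
        purity=1.0, wgd_flag=False,
    )


@pytest.fixture
def wgd_segment_4_2():
    """A clonal 4+2 segment in a WGD sample."""
    return SegmentState(
        chrom="8", start=1, end=10_000_000, states=[(4, 2, 1.0)],
        purity=1.0, wgd_flag=True,
    )


def supported_states():
    """Every supported (major, minor, wgd) combination with candidate orders."""
    states = [(major, minor, False) for major in range(2, 11) for minor in (0, 1)]
    states += [(major, minor, True) for major in range(2, 11) for minor in (0, 1, 2)]
    return states


def canonical_states():
    """The canonical timing series: major+1 without WGD, major+2 with WGD."""
    return [(major, 1, False) for major in range(2, 11)] + [
        (major, 2, True) for major in range(2, 11)
    ]
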