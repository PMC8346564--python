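import numpy as np
import pytest
from hypothesis import settings

from myelotrace.traces import AxonTrace, InternodeAnnotation, Polyline3D

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def straight_axon():
    """Unbranched 200 μm axon along x, points every 10 μm."""

    def make(length: float = 200.0, axon_id: str = "a0", subtype: str = "PV"):
        n = int(length // 10) + 1
        xs = np.linspace(0.0, length, n)
        pts = np.column_stack([xs, np.zeros(n), np.zeros(n)])
        return AxonTrace(
            axon_id=axon_id,
            subtype=subtype,
            region="SS",
            branches={"b0": Polyline3D(pts)},
            parents={"b0": None},
        )

    return make


@pytest.fixture
def ann():
    """Shorthand internode-annotation factory."""

    def make(s0, s1, axon_id="a0", branch_id="b0"):
        return InternodeAnnotation(axon_id, branch_id, s0, s1)

    return make


@pytest.fixture
def swc_file(tmp_path):
    """Write SWC text to a temp file and return its path."""

    def make(text, name="axon.swc"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return make
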