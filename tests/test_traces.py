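"""Trace model: SWC I/O, arc-length geometry, smoothing, annotations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from myelotrace.traces import (
    AnnotationError,
    DegenerateTraceError,
    InternodeAnnotation,
    LongitudinalRecord,
    Polyline3D,
    SWCParseError,
    SWCStructureError,
    arclength_interval_length,
    merge_annotations,
    read_annotations,
    read_longitudinal,
    read_swc,
    smooth_trace,
    write_annotations,
    write_longitudinal,
    write_swc,
)

UNBRANCHED = """# comment
1 0 0 0 0 0.5 -1
2 0 10 0 0 0.5 1
3 0 20 0 0 0.5 2
"""

BIFURCATED = """1 0 0 0 0 0.5 -1
2 0 10 0 0 0.5 1
3 0 20 0 0 0.5 2
4 0 30 5 0 0.5 3
5 0 30 -5 0 0.5 3
6 0 40 -10 0 0.5 5
"""


class TestReadSWC:
    def test_unbranched_three_nodes(self, swc_file):
        t = read_swc(swc_file(UNBRANCHED))
        assert len(t.branches) == 1
        assert t.total_length == pytest.approx(20.0)

    def test_bifurcation_splits_into_child_branches(self, swc_file):
        t = read_swc(swc_file(BIFURCATED))
        lengths = sorted(round(b.length, 6) for b in t.branches.values())
        # trunk 20; children sqrt(125) and sqrt(125)+sqrt(125)
        assert lengths == pytest.approx([np.sqrt(125), 20.0, 2 * np.sqrt(125)])
        roots = [b for b, p in t.parents.items() if p is None]
        assert len(roots) == 1
        # both children attach to the trunk
        trunk = roots[0]
        children = [b for b, p in t.parents.items() if p == trunk]
        assert len(children) == 2

    def test_missing_parent_is_structural_error(self, swc_file):
        bad = "1 0 0 0 0 0.5 -1\n2 0 1 0 0 0.5 9\n"
        with pytest.raises(SWCStructureError):
            read_swc(swc_file(bad))

    def test_malformed_line_reports_line_number(self, swc_file):
        bad = "1 0 0 0 0 0.5 -1\n2 0 oops 0 0 0.5 1\n"
        with pytest.raises(SWCParseError, match=":2"):
            read_swc(swc_file(bad))

    def test_single_node_is_degenerate(self, swc_file):
        with pytest.raises(DegenerateTraceError):
            read_swc(swc_file("1 0 0 0 0 0.5 -1\n"))

    @pytest.mark.parametrize("text", [UNBRANCHED, BIFURCATED])
    def test_roundtrip_preserves_geometry_and_topology(self, swc_file, tmp_path, text):
        t = read_swc(swc_file(text))
        out = tmp_path / "rt.swc"
        write_swc(t, out)
        t2 = read_swc(out)
        assert set(t.branches) == set(t2.branches)
        assert t.parents == t2.parents
        for bid in t.branches:
            np.testing.assert_allclose(t.branches[bid].points, t2.branches[bid].points)

    def test_branch_lengths_sum_to_total(self, swc_file):
        t = read_swc(swc_file(BIFURCATED))
        assert abs(sum(b.length for b in t.branches.values()) - t.total_length) < 1e-9


class TestSmoothing:
    def test_window_one_is_identity(self):
        poly = Polyline3D(np.array([[0, 0, 0], [1, 2, 3], [4, 0, 1]], float))
        assert smooth_trace(poly, 1) is poly

    def test_zigzag_shrinks(self):
        zig = Polyline3D(
            np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0], [4, 0, 0]], float)
        )
        sm = smooth_trace(zig, 3)
        assert sm.length < zig.length
        np.testing.assert_allclose(sm.points[0], zig.points[0])
        np.testing.assert_allclose(sm.points[-1], zig.points[-1])

    def test_straight_line_length_unchanged(self):
        xs = np.array([0.0, 3.0, 4.0, 9.0, 10.0])
        poly = Polyline3D(np.column_stack([xs, 2 * xs, -xs]))
        for w in (3, 5):
            assert smooth_trace(poly, w).length == pytest.approx(poly.length)

    def test_even_window_rejected(self):
        poly = Polyline3D(np.array([[0, 0, 0], [1, 0, 0]], float))
        with pytest.raises(ValueError):
            smooth_trace(poly, 2)

    @given(
        pts=arrays(
            float,
            st.tuples(st.integers(3, 25), st.just(3)),
            elements=st.floats(-100, 100, allow_nan=False),
        ),
        window=st.sampled_from([3, 5, 7]),
    )
    def test_never_increases_length(self, pts, window):
        try:
            poly = Polyline3D(pts)
        except Exception:
            return
        assert smooth_trace(poly, window).length <= poly.length + 1e-9


class TestAnnotations:
    def test_interval_length(self, ann):
        assert arclength_interval_length(ann(10, 60)) == 50

    def test_abutting_intervals_are_valid(self, ann):
        merged = merge_annotations([ann(0, 10), ann(10, 20)])
        assert [a.length for a in merged] == [10, 10]

    def test_small_overlap_merges(self, ann):
        merged = merge_annotations([ann(0, 10.3), ann(10.0, 20)])
        assert len(merged) == 1
        assert merged[0].length == pytest.approx(20)

    def test_large_overlap_rejected(self, ann):
        with pytest.raises(AnnotationError):
            merge_annotations([ann(0, 12), ann(10, 20)])

    def test_inverted_interval_rejected(self):
        with pytest.raises(AnnotationError):
            InternodeAnnotation("a", "b", 5, 5)

    def test_tsv_roundtrip(self, ann, tmp_path):
        anns = [ann(0, 10), ann(15, 40)]
        p = tmp_path / "ann.tsv"
        write_annotations(anns, p)
        assert read_annotations(p) == anns


class TestLongitudinalRecord:
    def test_status_consistency_enforced(self):
        with pytest.raises(ValueError):
            LongitudinalRecord("a", "PV", 0.0, 0.0, "present")
        with pytest.raises(ValueError):
            LongitudinalRecord("a", "PV", 10.0, 20.0, "excluded_always_unmyelinated")

    def test_plm_cap_bound(self):
        with pytest.raises(ValueError):
            LongitudinalRecord("a", "PV", 99.5, 10.0, "present")

    def test_tsv_roundtrip(self, tmp_path):
        recs = [
            LongitudinalRecord("a", "PV", 10.0, 30.0, "present"),
            LongitudinalRecord("b", "VM", 0.0, 0.0, "excluded_always_unmyelinated"),
        ]
        p = tmp_path / "long.tsv"
        write_longitudinal(recs, p)
        assert read_longitudinal(p) == recs


def test_unknown_subtype_rejected(straight_axon):
    with pytest.raises(ValueError, match="subtype"):
        straight_axon(subtype="L5")
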