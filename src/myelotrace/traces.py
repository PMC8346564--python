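"""Data model and I/O for axon traces, myelin annotations and tabular inputs.

An axon is represented as a tree of branches, each branch a 3D polyline with
cumulative arc length in micrometres.  Myelin internodes are stored as
arc-length intervals ``[s_start, s_end)`` on individual branches, which keeps
coverage geometry exact: percent length myelinated and gap lengths are pure
interval arithmetic on the branch parameterisation.

Supported on-disk formats:

* SWC (``id type x y z radius parent``) for axon morphology;
* TSV tables for internode annotations, longitudinal percent-length-myelinated
  (PLM) records, and sheath-count regions of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBTYPES",
    "REGIONS",
    "Polyline3D",
    "AxonTrace",
    "InternodeAnnotation",
    "LongitudinalRecord",
    "SheathROI",
    "SWCParseError",
    "SWCStructureError",
    "DegenerateTraceError",
    "AnnotationError",
    "read_swc",
    "write_swc",
    "smooth_trace",
    "arclength_interval_length",
    "merge_annotations",
    "read_annotations",
    "write_annotations",
    "read_longitudinal",
    "write_longitudinal",
    "read_sheath_rois",
    "write_sheath_rois",
]

#: Neuronal subtypes with axon collaterals in cortical layer I.  PV/SOM are
#: local interneurons, VM/PO thalamocortical projections, RBP4/NTSR1/NXPH4
#: layer V / VI / VIb pyramidal populations.  Closed enum so that dummy
#: coding in the myelination model is well defined.
SUBTYPES = ("PV", "SOM", "VM", "PO", "RBP4", "NXPH4", "NTSR1")

#: Cortical regions compared in the regional-scaling analysis.
REGIONS = ("SS", "VIS", "AUD", "MOs", "TEa", "other")

LONGITUDINAL_STATUSES = ("present", "lost", "excluded_always_unmyelinated")


class SWCParseError(ValueError):
    """Malformed SWC line (reported with its 1-based line number)."""


class SWCStructureError(ValueError):
    """SWC node graph is not a single rooted tree."""


class DegenerateTraceError(ValueError):
    """Trace has too few points to define a polyline."""


class AnnotationError(ValueError):
    """Internode annotation inconsistent with its axon/branch."""


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class Polyline3D:
    """An ordered 3D polyline in μm with precomputed cumulative arc length."""

    points: np.ndarray  # (n, 3) float array
    cumulative_arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if pts.shape[0] < 2:
            raise DegenerateTraceError("polyline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.cumulative_arclength is None:
            object.__setattr__(
                self, "cumulative_arclength", _cumulative_arclength(pts)
            )
        else:
            cum = np.asarray(self.cumulative_arclength, dtype=float)
            if cum.shape != (pts.shape[0],):
                raise ValueError("cumulative_arclength length mismatch")
            if cum[0] != 0.0 or np.any(np.diff(cum) < 0):
                raise ValueError("cumulative_arclength must be non-decreasing from 0")
            object.__setattr__(self, "cumulative_arclength", cum)

    @property
    def length(self) -> float:
        """Total arc length in μm."""
        return float(self.cumulative_arclength[-1])


@dataclass(frozen=True)
class AxonTrace:
    """A branched axon trace: branch_id → polyline plus tree connectivity.

    ``parents`` maps every branch id to its parent branch id (``None`` for
    the root branch); a child branch attaches at the last point of its
    parent, whose coordinate it repeats as its own first point.
    """

    axon_id: str
    subtype: str
    region: str
    branches: Mapping[str, Polyline3D]
    parents: Mapping[str, str | None]

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not self.branches:
            raise DegenerateTraceError("axon has no branches")
        if set(self.parents) != set(self.branches):
            raise SWCStructureError("parents must cover exactly the branch ids")
        # connectivity must be a tree: exactly one root, no cycles
        roots = [b for b, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root branch, got {len(roots)}")
        seen: set[str] = set()
        for b in self.branches:
            chain = []
            cur: str | None = b
            while cur is not None and cur not in seen:
                if cur in chain:
                    raise SWCStructureError("branch connectivity contains a cycle")
                chain.append(cur)
                cur = self.parents[cur]
                if cur is not None and cur not in self.branches:
                    raise SWCStructureError(f"parent branch {cur!r} does not exist")
            seen.update(chain)
        if self.total_length <= 0:
            raise DegenerateTraceError("axon total length must be positive")

    @property
    def total_length(self) -> float:
        """Summed arc length of all branches in μm."""
        return float(sum(b.length for b in self.branches.values()))


@dataclass(frozen=True)
class InternodeAnnotation:
    """One myelin internode as an arc-length interval on one branch.

    ``s_end`` may overshoot the branch length by at most 10% of it: separately
    traced myelin is slightly longer than the underlying axon trace when the
    myelin trace is more jagged, and that jitter is preserved rather than
    clipped so the downstream PLM cap rule can fire.
    """

    axon_id: str
    branch_id: str
    s_start: float
    s_end: float

    OVERSHOOT_FRAC = 0.10

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s_start) and math.isfinite(self.s_end)):
            raise AnnotationError("annotation bounds must be finite")
        if self.s_start < 0 or self.s_start >= self.s_end:
            raise AnnotationError(
                f"need 0 <= s_start < s_end, got [{self.s_start}, {self.s_end})"
            )

    @property
    def length(self) -> float:
        return self.s_end - self.s_start

    def validate_against(self, branch: Polyline3D) -> None:
        limit = branch.length * (1.0 + self.OVERSHOOT_FRAC)
        if self.s_end > limit + 1e-9:
            raise AnnotationError(
                f"annotation end {self.s_end:.3f} exceeds branch length "
                f"{branch.length:.3f} by more than {self.OVERSHOOT_FRAC:.0%}"
            )


def arclength_interval_length(ann: InternodeAnnotation) -> float:
    """Length in μm of one internode annotation (``s_end − s_start``)."""
    return ann.length


@dataclass(frozen=True)
class LongitudinalRecord:
    """Baseline/recovery PLM pair for one axon followed in vivo."""

    axon_id: str
    subtype: str
    plm_baseline: float
    plm_recovery: float
    status: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.status not in LONGITUDINAL_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        for v in (self.plm_baseline, self.plm_recovery):
            if not 0.0 <= v <= 99.0:
                raise ValueError(f"PLM {v} outside [0, 99] (cap rule)")
        both_zero = self.plm_baseline == 0.0 and self.plm_recovery == 0.0
        if (self.status == "excluded_always_unmyelinated") != both_zero and self.status != "lost":
            raise ValueError(
                "status must be excluded_always_unmyelinated iff both PLM values are 0"
            )


@dataclass(frozen=True)
class SheathROI:
    """Counts of PV vs other myelin sheaths in one imaging volume."""

    roi_id: str
    n_pv_sheaths: int
    n_other_sheaths: int
    timepoint: str

    def __post_init__(self) -> None:
        if self.n_pv_sheaths < 0 or self.n_other_sheaths < 0:
            raise ValueError("sheath counts must be non-negative")
        if self.timepoint not in ("baseline", "recovery"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


# ---------------------------------------------------------------------------
# SWC I/O


def _parse_swc_nodes(path: Path) -> dict[int, tuple[float, float, float, int]]:
    nodes: dict[int, tuple[float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
                float(parts[5])  # radius, ignored
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            if nid in nodes:
                raise SWCParseError(f"{path}:{lineno}: duplicate node id {nid}")
            nodes[nid] = (x, y, z, parent)
    return nodes


def read_swc(
    path: str | Path,
    axon_id: str | None = None,
    subtype: str = "PV",
    region: str = "SS",
) -> AxonTrace:
    """Read an SWC morphology file into an :class:`AxonTrace`.

    The tree is split into maximal unbranched paths between root, bifurcation
    and leaf nodes; each such path becomes one branch, repeating its parent's
    attachment point so branch geometry is continuous.  Coordinates are
    interpreted as μm; the type and radius columns are ignored.
    """
    path = Path(path)
    nodes = _parse_swc_nodes(path)
    if len(nodes) < 2:
        raise DegenerateTraceError(f"{path}: SWC has fewer than 2 nodes")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid, (_, _, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            if parent not in nodes:
                raise SWCStructureError(f"{path}: node {nid} references missing parent {parent}")
            children[parent].append(nid)
    if len(roots) != 1:
        raise SWCStructureError(f"{path}: expected exactly 1 root, found {len(roots)}")
    root = roots[0]
    for kids in children.values():
        kids.sort()

    coords = {nid: np.array(nodes[nid][:3]) for nid in nodes}
    branches: dict[str, Polyline3D] = {}
    parents: dict[str, str | None] = {}
    counter = 0
    # stack of (start node, parent branch id, attachment node id or None)
    stack: list[tuple[int, str | None, int | None]] = [(root, None, None)]
    visited = {root}
    while stack:
        start, parent_branch, attach = stack.pop()
        pts = [coords[attach]] if attach is not None else []
        cur = start
        while True:
            pts.append(coords[cur])
            kids = children[cur]
            if len(kids) != 1:
                break
            nxt = kids[0]
            if nxt in visited:
                raise SWCStructureError(f"{path}: cycle detected at node {nxt}")
            visited.add(nxt)
            cur = nxt
        if len(pts) >= 2:
            bid = f"b{counter}"
            counter += 1
            branches[bid] = Polyline3D(np.array(pts, dtype=float))
            parents[bid] = parent_branch
            owner = bid
        else:
            # a root that immediately bifurcates: children hang off the root
            # coordinate directly and the root itself forms no branch
            owner = parent_branch
        for nxt in reversed(children[cur]):
            if nxt in visited:
                raise SWCStructureError(f"{path}: cycle detected at node {nxt}")
            visited.add(nxt)
            stack.append((nxt, owner, cur))
    if len(visited) != len(nodes):
        raise SWCStructureError(f"{path}: {len(nodes) - len(visited)} nodes unreachable from root")

    # a bifurcating root produces child branches whose parent is None
    if not branches:
        raise DegenerateTraceError(f"{path}: no branch with >= 2 nodes")
    n_roots = sum(1 for p in parents.values() if p is None)
    if n_roots > 1:
        # attach sibling root branches under the first so connectivity is a tree
        root_bids = [b for b, p in parents.items() if p is None]
        anchor = root_bids[0]
        for other in root_bids[1:]:
            parents[other] = anchor

    return AxonTrace(
        axon_id=axon_id if axon_id is not None else path.stem,
        subtype=subtype,
        region=region,
        branches=branches,
        parents=parents,
    )


def write_swc(trace: AxonTrace, path: str | Path) -> None:
    """Write an :class:`AxonTrace` as SWC (inverse of :func:`read_swc`)."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    next_id = 1
    # branch id -> SWC id of its last point
    tip_ids: dict[str, int] = {}
    order = _topological_branch_order(trace)
    for bid in order:
        poly = trace.branches[bid]
        parent_branch = trace.parents[bid]
        if parent_branch is None:
            parent_swc = -1
            pts = poly.points
        else:
            parent_swc = tip_ids[parent_branch]
            pts = poly.points[1:]  # first point repeats the attachment point
        for p in pts:
            lines.append(
                f"{next_id} 0 {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} 0.5 {parent_swc}"
            )
            parent_swc = next_id
            next_id += 1
        tip_ids[bid] = parent_swc
    path.write_text("\n".join(lines) + "\n")


def _topological_branch_order(trace: AxonTrace) -> list[str]:
    order: list[str] = []
    remaining = set(trace.branches)
    placed: set[str] = set()
    while remaining:
        progressed = False
        for bid in sorted(remaining):
            parent = trace.parents[bid]
            if parent is None or parent in placed:
                order.append(bid)
                placed.add(bid)
                remaining.discard(bid)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by AxonTrace invariant
            raise SWCStructureError("branch connectivity is not a tree")
    return order


# ---------------------------------------------------------------------------
# Smoothing


def smooth_trace(poly: Polyline3D, window: int = 3) -> Polyline3D:
    """Moving-average smoothing of a polyline with endpoint preservation.

    Each interior point is replaced by the mean of a centred window of up to
    ``window`` points, symmetrically shrunk near the ends so the first and
    last points are unchanged.  ``window=1`` is the identity.  Smoothing is a
    contraction on jagged paths, so it never increases total arc length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if window == 1:
        return poly
    pts = poly.points
    n = pts.shape[0]
    half = window // 2
    out = np.empty_like(pts)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = pts[i - h : i + h + 1].mean(axis=0)
    return Polyline3D(out)


# ---------------------------------------------------------------------------
# Annotation handling and TSV I/O

#: overlaps up to this arc length (μm) are treated as rounding at shared
#: node boundaries and merged; anything larger is inconsistent input
MERGE_TOLERANCE_UM = 0.5


def merge_annotations(
    annotations: Iterable[InternodeAnnotation],
    tolerance: float = MERGE_TOLERANCE_UM,
) -> list[InternodeAnnotation]:
    """Sort annotations on one branch and merge small boundary overlaps.

    Overlaps of at most ``tolerance`` μm are merged into a single internode;
    larger overlaps raise :class:`AnnotationError`.
    """
    anns = sorted(annotations, key=lambda a: (a.s_start, a.s_end))
    if not anns:
        return []
    key = (anns[0].axon_id, anns[0].branch_id)
    for a in anns[1:]:
        if (a.axon_id, a.branch_id) != key:
            raise AnnotationError("merge_annotations expects annotations on one branch")
    merged = [anns[0]]
    for a in anns[1:]:
        prev = merged[-1]
        overlap = prev.s_end - a.s_start
        if overlap > tolerance + 1e-12:
            raise AnnotationError(
                f"annotations on {key} overlap by {overlap:.3f} μm (> {tolerance} μm)"
            )
        if overlap > 0:
            merged[-1] = InternodeAnnotation(
                prev.axon_id, prev.branch_id, prev.s_start, max(prev.s_end, a.s_end)
            )
        else:
            merged.append(a)
    return merged


def read_annotations(path: str | Path) -> list[InternodeAnnotation]:
    """Read the internode TSV (`axon_id branch_id s_start_um s_end_um`)."""
    df = pd.read_csv(path, sep="\t")
    required = {"axon_id", "branch_id", "s_start_um", "s_end_um"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return [
        InternodeAnnotation(str(r.axon_id), str(r.branch_id), float(r.s_start_um), float(r.s_end_um))
        for r in df.itertuples()
    ]


def write_annotations(annotations: Sequence[InternodeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "axon_id": [a.axon_id for a in annotations],
            "branch_id": [a.branch_id for a in annotations],
            "s_start_um": [a.s_start for a in annotations],
            "s_end_um": [a.s_end for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_longitudinal(path: str | Path) -> list[LongitudinalRecord]:
    """Read the longitudinal TSV (`axon_id subtype plm_baseline plm_recovery status`)."""
    df = pd.read_csv(path, sep="\t")
    return [
        LongitudinalRecord(
            str(r.axon_id), str(r.subtype), float(r.plm_baseline), float(r.plm_recovery), str(r.status)
        )
        for r in df.itertuples()
    ]


def write_longitudinal(records: Sequence[LongitudinalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "axon_id": [r.axon_id for r in records],
            "subtype": [r.subtype for r in records],
            "plm_baseline": [r.plm_baseline for r in records],
            "plm_recovery": [r.plm_recovery for r in records],
            "status": [r.status for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sheath_rois(path: str | Path) -> list[SheathROI]:
    """Read the ROI sheath TSV (`roi_id timepoint n_pv n_other`)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SheathROI(str(r.roi_id), int(r.n_pv), int(r.n_other), str(r.timepoint))
        for r in df.itertuples()
    ]


def write_sheath_rois(rois: Sequence[SheathROI], path: str | Path) -> None:
    pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "timepoint": [r.timepoint for r in rois],
            "n_pv": [r.n_pv_sheaths for r in rois],
            "n_other": [r.n_other_sheaths for r in rois],
        }
    ).to_csv(path, sep="\t", index=False)
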