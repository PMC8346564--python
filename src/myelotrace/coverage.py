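"""Per-axon myelin coverage statistics.

The central quantity is the percent of axon length myelinated,

    PLM = 100 × (summed internode length) / (total axon length),

computed on the pooled branch tree of each axon.  Because axon and myelin
traces originate from different image channels, jitter can push the raw
quotient above 100%; such values are capped at 99% by convention.  Gaps are
the unmyelinated stretches between consecutive internodes on one branch and
are classified as nodal (length ≤ 5 μm, the typical maximum extent of a node
of Ranvier) or non-nodal (> 5 μm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traces import (
    AnnotationError,
    AxonTrace,
    InternodeAnnotation,
    merge_annotations,
)

__all__ = [
    "NODAL_THRESHOLD_UM",
    "PLM_CAP_PERCENT",
    "Gap",
    "MyelinationProfile",
    "RegionalSummary",
    "compute_plm",
    "extract_gaps",
    "proportion_myelinated",
    "scaled_prevalence",
    "select_axon_seeds",
    "profiles_to_frame",
    "gaps_to_frame",
]

#: gaps at or below this arc length (μm) are nodes of Ranvier
NODAL_THRESHOLD_UM = 5.0

#: PLM assigned when trace jitter pushes the raw quotient above 100%
PLM_CAP_PERCENT = 99.0


@dataclass(frozen=True)
class Gap:
    """One unmyelinated stretch between two consecutive internodes."""

    length: float
    nodal: bool


@dataclass(frozen=True)
class MyelinationProfile:
    """Derived per-axon myelination record."""

    axon_id: str
    total_length: float
    myelinated_length: float
    plm: float
    internode_lengths: tuple[float, ...]
    gaps: tuple[Gap, ...]

    @property
    def is_myelinated(self) -> bool:
        return self.plm > 0


@dataclass(frozen=True)
class RegionalSummary:
    """Regional myelin density scaled by the proportion of axons myelinated."""

    region: str
    mbp_intensity: float
    proportion_myelinated: float
    scaled_prevalence: float


def extract_gaps(
    annotations: Sequence[InternodeAnnotation],
    nodal_threshold: float = NODAL_THRESHOLD_UM,
) -> list[Gap]:
    """Gaps between consecutive internodes on one branch.

    Terminal unmyelinated stretches (before the first internode and after the
    last) are not gaps: a gap is the axonal distance between two consecutive
    myelin segments.  Nodal ⇔ length ≤ ``nodal_threshold``.
    """
    anns = sorted(annotations, key=lambda a: a.s_start)
    gaps: list[Gap] = []
    for prev, nxt in zip(anns, anns[1:]):
        g = nxt.s_start - prev.s_end
        if g <= 0:
            raise AnnotationError("annotations must be non-overlapping to extract gaps")
        gaps.append(Gap(length=g, nodal=g <= nodal_threshold))
    return gaps


def compute_plm(
    axon: AxonTrace,
    annotations: Iterable[InternodeAnnotation],
    cap_percent: float = PLM_CAP_PERCENT,
    nodal_threshold: float = NODAL_THRESHOLD_UM,
) -> MyelinationProfile:
    """Percent length myelinated and gap spectrum for one axon.

    Annotations are grouped per branch, merged at shared node boundaries
    (overlaps ≤ 0.5 μm) and validated against branch arc length.  The PLM is
    computed on the pooled tree — total myelin over total axon length — and
    capped at ``cap_percent`` when the raw quotient exceeds 100%.
    """
    per_branch: dict[str, list[InternodeAnnotation]] = {}
    for ann in annotations:
        if ann.axon_id != axon.axon_id:
            raise AnnotationError(
                f"annotation for axon {ann.axon_id!r} passed with axon {axon.axon_id!r}"
            )
        if ann.branch_id not in axon.branches:
            raise AnnotationError(
                f"axon {axon.axon_id!r} has no branch {ann.branch_id!r}"
            )
        per_branch.setdefault(ann.branch_id, []).append(ann)

    internode_lengths: list[float] = []
    gaps: list[Gap] = []
    for bid in sorted(per_branch):
        merged = merge_annotations(per_branch[bid])
        for ann in merged:
            ann.validate_against(axon.branches[bid])
        internode_lengths.extend(a.length for a in merged)
        gaps.extend(extract_gaps(merged, nodal_threshold=nodal_threshold))

    total = axon.total_length
    myelinated = float(sum(internode_lengths))
    raw = 100.0 * myelinated / total
    plm = cap_percent if raw > 100.0 else raw
    return MyelinationProfile(
        axon_id=axon.axon_id,
        total_length=total,
        myelinated_length=myelinated,
        plm=plm,
        internode_lengths=tuple(internode_lengths),
        gaps=tuple(gaps),
    )


def proportion_myelinated(
    profiles: Sequence[MyelinationProfile],
    animals: Sequence[str] | None = None,
) -> float | tuple[float, float]:
    """Fraction of axons with any myelin (PLM > 0).

    Without grouping, returns the pooled fraction.  With ``animals`` (one
    label per profile), returns ``(mean, sem)`` of per-animal fractions —
    the unit of replication is the mouse, matching how population
    proportions are reported per N animals.
    """
    if not profiles:
        raise ValueError("no profiles given")
    flags = np.array([p.is_myelinated for p in profiles], dtype=float)
    if animals is None:
        return float(flags.mean())
    if len(animals) != len(profiles):
        raise ValueError("animals must be parallel to profiles")
    frame = pd.DataFrame({"animal": list(animals), "myelinated": flags})
    per_animal = frame.groupby("animal")["myelinated"].mean()
    mean = float(per_animal.mean())
    sem = float(per_animal.std(ddof=1) / np.sqrt(len(per_animal))) if len(per_animal) > 1 else 0.0
    return mean, sem


def scaled_prevalence(mbp_intensity: float, proportion_myelinated: float) -> float:
    """Regional myelin density scaled to the proportion of axons myelinated.

    scaled prevalence = (average binarized MBP intensity) / (proportion of
    axons myelinated).  Undefined when no axon is myelinated.
    """
    if proportion_myelinated <= 0:
        raise ZeroDivisionError(
            "scaled prevalence undefined when the proportion myelinated is 0"
        )
    return mbp_intensity / proportion_myelinated


def select_axon_seeds(
    image_extent: tuple[float, float],
    n: int,
    grid_pitch: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Random grid-cell origins for unbiased axon seeding.

    A ``grid_pitch`` × ``grid_pitch`` μm grid is placed across the image with
    cells anchored at multiples of the pitch from the origin; partially
    covered edge cells count.  ``n`` distinct cells are drawn uniformly
    without replacement, deterministically for a given seed.
    """
    width, height = image_extent
    if width <= 0 or height <= 0:
        raise ValueError("image extent must be positive")
    nx = int(np.ceil(width / grid_pitch))
    ny = int(np.ceil(height / grid_pitch))
    n_cells = nx * ny
    if n > n_cells:
        raise ValueError(f"requested {n} seeds but the grid has only {n_cells} cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = rng.choice(n_cells, size=n, replace=False)
    return [(float((c % nx) * grid_pitch), float((c // nx) * grid_pitch)) for c in chosen]


def profiles_to_frame(
    profiles: Sequence[MyelinationProfile],
    subtypes: Mapping[str, str] | None = None,
    regions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate profiles as `axon_id subtype region total_length_um plm n_internodes`."""
    return pd.DataFrame(
        {
            "axon_id": [p.axon_id for p in profiles],
            "subtype": [(subtypes or {}).get(p.axon_id, "") for p in profiles],
            "region": [(regions or {}).get(p.axon_id, "") for p in profiles],
            "total_length_um": [p.total_length for p in profiles],
            "plm": [p.plm for p in profiles],
            "n_internodes": [len(p.internode_lengths) for p in profiles],
        }
    )


def gaps_to_frame(profiles: Sequence[MyelinationProfile]) -> pd.DataFrame:
    """Tabulate all gaps as `axon_id gap_um nodal`."""
    rows = [
        {"axon_id": p.axon_id, "gap_um": g.length, "nodal": g.nodal}
        for p in profiles
        for g in p.gaps
    ]
    return pd.DataFrame(rows, columns=["axon_id", "gap_um", "nodal"])
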