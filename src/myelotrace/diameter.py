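"""Axon diameter estimation from transverse intensity profiles.

A transverse profile of fluorescence intensity across an axon (each value the
mean gray value over a ~2 μm stretch along the axon) is reduced to a diameter
by full width at half maximum (FWHM): the baseline is the profile minimum,
the half-max level sits midway between baseline and peak, and the width is
measured between the half-max crossings adjacent to the global peak, located
by linear interpolation between samples.  Two to three sites per axon are
averaged into a per-axon mean diameter, and the fraction of myelinated sites
gives the axon's (possibly fractional) myelination response for the
diameter+subtype logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityProfile",
    "DiameterRecord",
    "DegenerateProfileError",
    "InsufficientSitesError",
    "fwhm",
    "axon_diameter",
    "read_profiles",
    "diameter_records_to_frame",
]


class DegenerateProfileError(ValueError):
    """Profile carries no usable peak (flat, or never falls to half max)."""


class InsufficientSitesError(ValueError):
    """Fewer measurement sites than required for a per-axon average."""


@dataclass(frozen=True)
class IntensityProfile:
    """One transverse intensity profile at one measurement site."""

    positions: np.ndarray  # μm offsets across the axon, strictly increasing
    values: np.ndarray  # mean gray values
    site_myelinated: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or pos.shape != val.shape:
            raise ValueError("positions and values must be 1D arrays of equal length")
        if pos.size < 5:
            raise ValueError("profile needs at least 5 samples")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(val))):
            raise ValueError("profile samples must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class DiameterRecord:
    """Per-axon aggregate of site FWHM diameters and myelination status."""

    axon_id: str
    subtype: str
    site_diameters: tuple[float, ...]
    mean_diameter: float
    myelination_fraction: float


def _cross(x0: float, y0: float, x1: float, y1: float, level: float) -> float:
    # linear interpolation of the crossing of `level` between two samples
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def fwhm(profile: IntensityProfile) -> float:
    """Full width at half maximum of a transverse intensity profile in μm.

    Baseline = profile minimum (fluorescence rides on background), half-max
    level = baseline + (peak − baseline)/2.  With noisy shoulders there can
    be several crossings of the half-max level; the crossings adjacent to
    the global peak are used, measuring the central lobe.  Invariant to
    additive baseline shifts and multiplicative scaling.
    """
    pos, val = profile.positions, profile.values
    baseline = float(val.min())
    peak_idx = int(val.argmax())
    peak = float(val[peak_idx])
    if peak == baseline:
        raise DegenerateProfileError("flat profile: max equals min")
    level = baseline + (peak - baseline) / 2.0

    left = None
    for i in range(peak_idx, 0, -1):
        if val[i - 1] < level <= val[i]:
            left = _cross(pos[i - 1], val[i - 1], pos[i], val[i], level)
            break
    right = None
    for i in range(peak_idx, len(val) - 1):
        if val[i] >= level > val[i + 1]:
            right = _cross(pos[i], val[i], pos[i + 1], val[i + 1], level)
            break
    if left is None or right is None:
        raise DegenerateProfileError(
            "profile does not fall below half max on both sides of the peak"
        )
    return right - left


def axon_diameter(
    profiles: Sequence[IntensityProfile],
    axon_id: str = "",
    subtype: str = "",
) -> DiameterRecord:
    """Average site FWHMs into one diameter and site-myelination fraction.

    The myelination fraction is (# myelinated sites)/(total sites) — the
    mean of the per-site boolean flags — and is an intermediate value
    (1/k, 2/k, …) when sites along one axon disagree.
    """
    if len(profiles) < 2:
        raise InsufficientSitesError(
            f"need at least 2 measurement sites, got {len(profiles)}"
        )
    diams = tuple(fwhm(p) for p in profiles)
    flags = [p.site_myelinated for p in profiles]
    return DiameterRecord(
        axon_id=axon_id,
        subtype=subtype,
        site_diameters=diams,
        mean_diameter=float(np.mean(diams)),
        myelination_fraction=float(np.mean(flags)),
    )


def read_profiles(path: str | Path) -> dict[tuple[str, str], IntensityProfile]:
    """Read the site TSV (`axon_id site_id position_um value myelinated`).

    Returns a mapping (axon_id, site_id) → profile.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], IntensityProfile] = {}
    for (axon, site), grp in df.groupby(["axon_id", "site_id"], sort=True):
        grp = grp.sort_values("position_um")
        myel = bool(grp["myelinated"].iloc[0])
        out[(str(axon), str(site))] = IntensityProfile(
            positions=grp["position_um"].to_numpy(),
            values=grp["value"].to_numpy(),
            site_myelinated=myel,
        )
    return out


def diameter_records_to_frame(records: Sequence[DiameterRecord]) -> pd.DataFrame:
    """Tabulate as `axon_id subtype mean_diameter_um n_sites myelination_fraction`."""
    return pd.DataFrame(
        {
            "axon_id": [r.axon_id for r in records],
            "subtype": [r.subtype for r in records],
            "mean_diameter_um": [r.mean_diameter for r in records],
            "n_sites": [len(r.site_diameters) for r in records],
            "myelination_fraction": [r.myelination_fraction for r in records],
        }
    )
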