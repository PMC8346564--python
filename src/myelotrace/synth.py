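"""Seedable generators of synthetic axon-myelination data.

Every pipeline stage can be exercised without microscopy data by generating
inputs with the statistical structure the analysis assumes:

* per-subtype axon diameters (lognormal, matched mean/SD);
* myelination decided by the diameter+subtype logistic model;
* internode/gap structure along each myelinated axon, with short nodal gaps
  (≤ 5 μm, nodes of Ranvier) dominating and longer non-nodal gaps broadly
  distributed between 5 and 150 μm;
* transverse intensity profiles (box of width = diameter convolved with a
  Gaussian point-spread function plus noise) for FWHM diameter estimation;
* longitudinal remodeling in which weakly myelinated axons tend to gain
  myelin during recovery and continuously myelinated axons tend to lose it.

Where the underlying study reports a quantity (diameter means, the logistic
coefficients, the nodal fraction of gaps), defaults follow it; distributional
choices it does not report (internode lengths, the non-nodal gap law) are
synthetic defaults documented as such in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .diameter import IntensityProfile
from .glm import LAYER1_GLM_COEFFICIENTS
from .traces import (
    SUBTYPES,
    AxonTrace,
    InternodeAnnotation,
    LongitudinalRecord,
    Polyline3D,
)

__all__ = [
    "SubtypeParams",
    "RemodelingParams",
    "DEFAULT_SUBTYPE_PARAMS",
    "default_glm_coefficients",
    "gen_axon_population",
    "gen_intensity_profiles",
    "gen_longitudinal",
    "simulate_glm_dataset",
]


@dataclass(frozen=True)
class SubtypeParams:
    """Generative parameters for one neuronal subtype.

    ``beta_type`` is the subtype's logit offset in the myelination model
    (0 for the reference subtype).  Internode and gap parameters are
    synthetic defaults; the nodal gap range must lie within (0, 5] μm.
    """

    subtype: str
    diameter_mean: float  # μm
    diameter_sd: float  # μm
    beta_type: float
    internode_mean: float = 50.0  # μm, synthetic default
    internode_sd: float = 15.0
    internode_min: float = 10.0
    nodal_gap_range: tuple[float, float] = (0.5, 5.0)
    nonnodal_gap_logmean: float = 3.1  # log μm (median ≈ 22 μm)
    nonnodal_gap_logsd: float = 0.9
    p_nodal: float = 0.7

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise ValueError("diameter_mean must be > 0 and diameter_sd >= 0")
        if not 0.0 <= self.p_nodal <= 1.0:
            raise ValueError("p_nodal must lie in [0, 1]")
        lo, hi = self.nodal_gap_range
        if not (0.0 < lo < hi <= 5.0):
            raise ValueError("nodal_gap_range must lie within (0, 5] μm")
        if self.internode_min <= 0 or self.internode_mean <= 0:
            raise ValueError("internode lengths must be positive")


@dataclass(frozen=True)
class RemodelingParams:
    """Linear remodeling rule for longitudinal recovery.

    Expected ΔPLM declines linearly from ``gain_at_zero`` at baseline 0 to 0
    at ``pivot``, then continues linearly to ``−loss_at_full`` at baseline
    100, with Gaussian noise of SD ``noise_sd`` percentage points.
    """

    gain_at_zero: float = 20.0
    loss_at_full: float = 10.0
    noise_sd: float = 10.0
    pivot: float = 50.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.pivot < 100.0:
            raise ValueError("pivot must lie in (0, 100)")

    def expected_delta(self, baseline: float) -> float:
        if baseline < self.pivot:
            return self.gain_at_zero * (1.0 - baseline / self.pivot)
        return -self.loss_at_full * (baseline - self.pivot) / (100.0 - self.pivot)


def _default_params() -> dict[str, SubtypeParams]:
    # diameter means: PV 0.6 and VM 0.5 μm follow the reported subtype
    # averages; the remaining means and all SDs are synthetic defaults.
    means = {
        "PV": 0.60,
        "VM": 0.50,
        "SOM": 0.50,
        "PO": 0.50,
        "RBP4": 0.55,
        "NXPH4": 0.55,
        "NTSR1": 0.50,
    }
    betas = {
        "PV": 0.0,
        "VM": LAYER1_GLM_COEFFICIENTS["type_VM"][0],
        "PO": LAYER1_GLM_COEFFICIENTS["type_PO"][0],
        "RBP4": LAYER1_GLM_COEFFICIENTS["type_RBP4"][0],
        "NXPH4": LAYER1_GLM_COEFFICIENTS["type_NXPH4"][0],
        "NTSR1": LAYER1_GLM_COEFFICIENTS["type_NTSR1"][0],
        # SOM has no published coefficient (pooled with PO-like behaviour);
        # synthetic default reuses the PO offset.
        "SOM": LAYER1_GLM_COEFFICIENTS["type_PO"][0],
    }
    return {
        s: SubtypeParams(subtype=s, diameter_mean=means[s], diameter_sd=0.15, beta_type=betas[s])
        for s in SUBTYPES
    }


#: per-subtype generative defaults keyed by subtype label
DEFAULT_SUBTYPE_PARAMS: dict[str, SubtypeParams] = _default_params()


def default_glm_coefficients() -> dict[str, float]:
    """Generative logistic coefficients (point estimates of the published fit)."""
    return {t: v[0] for t, v in LAYER1_GLM_COEFFICIENTS.items()}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a lognormal to the requested mean and SD
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    # rejection sampling; cheap for the mild truncations used here
    while True:
        v = rng.normal(mean, sd)
        if v >= low:
            return v


def _straight_trace(axon_id: str, subtype: str, region: str, length: float, step: float = 5.0) -> AxonTrace:
    n = max(2, int(math.ceil(length / step)) + 1)
    xs = np.linspace(0.0, length, n)
    pts = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    return AxonTrace(
        axon_id=axon_id,
        subtype=subtype,
        region=region,
        branches={"b0": Polyline3D(pts)},
        parents={"b0": None},
    )


def _draw_gap(rng: np.random.Generator, p: SubtypeParams) -> float:
    if rng.uniform() < p.p_nodal:
        return rng.uniform(*p.nodal_gap_range)
    # lognormal truncated to the non-nodal range (5, 150] μm
    while True:
        gap = rng.lognormal(p.nonnodal_gap_logmean, p.nonnodal_gap_logsd)
        if 5.0 < gap <= 150.0:
            return gap


def _lay_internodes(
    rng: np.random.Generator, length: float, p: SubtypeParams
) -> list[tuple[float, float]]:
    """Alternate internodes and gaps along a branch of the given length.

    The trace is assumed to start mid-gap: the first internode begins at a
    uniformly drawn point within one mixture-drawn gap, so continuously
    myelinated parameterisations (p_nodal = 1, short nodal gaps) produce
    near-complete coverage.
    """
    intervals: list[tuple[float, float]] = []
    s = rng.uniform(0.0, min(_draw_gap(rng, p), length))
    while s < length:
        inter = _truncated_normal(rng, p.internode_mean, p.internode_sd, p.internode_min)
        end = min(s + inter, length)
        if end - s >= 1.0:  # drop sub-μm slivers at the branch end
            intervals.append((s, end))
        if end >= length:
            break
        s = end + _draw_gap(rng, p)
    return intervals


def gen_axon_population(
    params: Sequence[SubtypeParams] | Mapping[str, SubtypeParams] | None = None,
    glm_coefficients: Mapping[str, float] | None = None,
    n_per_subtype: int = 60,
    seed: int | np.random.Generator = 0,
    trace_length_mean: float = 400.0,
    trace_length_sd: float = 100.0,
    trace_length_min: float = 100.0,
    region: str = "SS",
    jitter_sd: float = 0.0,
) -> tuple[list[AxonTrace], list[InternodeAnnotation], pd.DataFrame]:
    """Generate a population of unbranched axons with internode annotations.

    For each axon, a diameter is drawn from the subtype's lognormal law, a
    straight trace of truncated-normal length is built, and the axon is
    myelinated with probability logistic(β0 + βd·diameter + βtype).  If
    myelinated, internodes alternate with nodal/non-nodal gaps from a uniform
    start offset to the branch end.

    ``jitter_sd`` > 0 emulates myelin-trace jitter: the axon trace is shrunk
    by a per-axon factor 1/(1+ε), ε ~ |N(0, jitter_sd)| capped at 9%, while
    annotation arc lengths are kept, so fully myelinated axons can carry more
    annotated myelin than trace length (exercising the 99% PLM cap).

    Returns (traces, annotations, diameter table) with columns
    ``axon_id subtype diameter_um myelinated``.
    """
    if params is None:
        params = DEFAULT_SUBTYPE_PARAMS
    if isinstance(params, Mapping):
        params = list(params.values())
    coefs = dict(glm_coefficients or default_glm_coefficients())
    if "(Intercept)" not in coefs or "diam" not in coefs:
        raise ValueError("glm_coefficients must include '(Intercept)' and 'diam'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    traces: list[AxonTrace] = []
    annotations: list[InternodeAnnotation] = []
    rows = []
    for p in params:
        mu, sigma = _lognormal_params(p.diameter_mean, p.diameter_sd)
        for i in range(n_per_subtype):
            axon_id = f"{p.subtype}_{i:05d}"
            diameter = float(rng.lognormal(mu, sigma))
            length = _truncated_normal(rng, trace_length_mean, trace_length_sd, trace_length_min)
            eta = coefs["(Intercept)"] + coefs["diam"] * diameter + p.beta_type
            myelinated = rng.uniform() < 1.0 / (1.0 + math.exp(-eta))
            intervals = _lay_internodes(rng, length, p) if myelinated else []
            if jitter_sd > 0:
                eps = min(abs(rng.normal(0.0, jitter_sd)), 0.09)
                length = length / (1.0 + eps)
            traces.append(_straight_trace(axon_id, p.subtype, region, length))
            annotations.extend(
                InternodeAnnotation(axon_id, "b0", s0, s1) for s0, s1 in intervals
            )
            rows.append(
                {
                    "axon_id": axon_id,
                    "subtype": p.subtype,
                    "diameter_um": diameter,
                    "myelinated": bool(myelinated),
                }
            )
    return traces, annotations, pd.DataFrame(rows, columns=["axon_id", "subtype", "diameter_um", "myelinated"])


def gen_intensity_profiles(
    diameters: Sequence[float],
    psf_sigma: float = 0.1,
    noise_sd: float = 0.05,
    samples_per_um: float = 20.0,
    seed: int | np.random.Generator = 0,
    baseline: float = 10.0,
    amplitude: float = 100.0,
    myelinated: Sequence[bool] | None = None,
) -> list[IntensityProfile]:
    """Transverse intensity profiles: box ⊗ Gaussian PSF + baseline + noise.

    Each profile is the exact convolution of a rectangular cross-section of
    width = diameter with a Gaussian of SD ``psf_sigma`` (closed erf form;
    ``psf_sigma=0`` gives the pure box), on a constant baseline, with i.i.d.
    Gaussian noise of SD ``noise_sd`` × amplitude.
    """
    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flags = list(myelinated) if myelinated is not None else [False] * len(diameters)
    out: list[IntensityProfile] = []
    for d, flag in zip(diameters, flags):
        half_extent = d / 2.0 + 4.0 * psf_sigma + 0.5
        n = max(5, int(round(2 * half_extent * samples_per_um)) + 1)
        x = np.linspace(-half_extent, half_extent, n)
        if psf_sigma == 0:
            signal = ((x >= -d / 2.0) & (x <= d / 2.0)).astype(float)
        else:
            s = psf_sigma * math.sqrt(2.0)
            signal = 0.5 * (erf((x + d / 2.0) / s) - erf((x - d / 2.0) / s))
        values = baseline + amplitude * signal
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd * amplitude, size=n)
        out.append(IntensityProfile(positions=x, values=values, site_myelinated=bool(flag)))
    return out


def gen_longitudinal(
    baseline_plms: Sequence[float],
    remodeling: RemodelingParams | None = None,
    seed: int | np.random.Generator = 0,
    subtype: str = "PV",
) -> list[LongitudinalRecord]:
    """Longitudinal records under the linear gain/loss remodeling rule.

    Recovery PLM = baseline + expected ΔPLM(baseline) + Gaussian noise,
    clipped to [0, 99].  Records unmyelinated at both timepoints get status
    ``excluded_always_unmyelinated`` (they are dropped from linear models).
    """
    remodeling = remodeling or RemodelingParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[LongitudinalRecord] = []
    for i, b in enumerate(baseline_plms):
        if not 0.0 <= b <= 99.0:
            raise ValueError(f"baseline PLM {b} outside [0, 99]")
        delta = remodeling.expected_delta(b)
        noise = rng.normal(0.0, remodeling.noise_sd) if remodeling.noise_sd > 0 else 0.0
        recovery = float(np.clip(b + delta + noise, 0.0, 99.0))
        status = (
            "excluded_always_unmyelinated" if b == 0.0 and recovery == 0.0 else "present"
        )
        records.append(
            LongitudinalRecord(
                axon_id=f"{subtype}_long_{i:05d}",
                subtype=subtype,
                plm_baseline=b,
                plm_recovery=recovery,
                status=status,
            )
        )
    return records


def simulate_glm_dataset(
    coefficients: Mapping[str, float] | None = None,
    n: int = 20000,
    seed: int | np.random.Generator = 0,
    diameter_range: tuple[float, float] = (0.2, 1.2),
    subtypes: Sequence[str] = ("PV", "VM", "PO", "RBP4", "NXPH4"),
) -> list[tuple[float, str, float]]:
    """Bernoulli draws from the logistic model for parameter-recovery studies.

    Diameters are uniform on ``diameter_range`` and subtypes uniform over
    ``subtypes``; outcomes are Bernoulli with probability
    logistic(β0 + βd·diameter + βtype).  Returns ``fit_myelination_glm``
    input triples.
    """
    coefs = dict(coefficients or default_glm_coefficients())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diam = rng.uniform(*diameter_range, size=n)
    subs = rng.choice(list(subtypes), size=n)
    beta_t = np.array([coefs.get(f"type_{s}", 0.0) for s in subs])
    eta = coefs["(Intercept)"] + coefs["diam"] * diam + beta_t
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return list(zip(diam.tolist(), subs.tolist(), y.tolist()))
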