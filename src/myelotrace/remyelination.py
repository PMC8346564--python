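"""Longitudinal baseline-vs-recovery myelination analysis.

After a demyelinating insult and recovery, each tracked axon contributes a
(baseline PLM, recovery PLM) pair.  ΔPLM = recovery − baseline, in
percentage points: −100 is full loss of a fully myelinated axon, +100 an
unmyelinated axon that became fully myelinated.  Two linear models relate
recovery to baseline:

* simple:    recovery ~ 1 + baseline
* adjusted:  recovery ~ 1 + baseline + baseline:ΔPLM

The adjusted form includes the realized ΔPLM of each axon as an interaction
regressor.  Note that ΔPLM is itself a function of the response (recovery −
baseline), which makes the adjusted model near-circular and its R²
optimistic by construction; the form is reproduced verbatim because it is
the analysis under study, not a corrected one.

Axons that remained unmyelinated at both timepoints are excluded from the
linear models (they carry no remodeling information and would anchor the fit
at the origin), and lost axons are excluded from everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .traces import LongitudinalRecord, SheathROI

__all__ = [
    "RemyelinationModelFit",
    "SheathFractionSummary",
    "ExcludedRecordError",
    "delta_plm",
    "fit_recovery_model",
    "identity_crossing",
    "tracing_error_band",
    "pv_sheath_fraction",
]


class ExcludedRecordError(ValueError):
    """Operation requested on a record excluded from analysis."""


@dataclass(frozen=True)
class RemyelinationModelFit:
    """OLS fit of recovery PLM on baseline PLM (optionally ΔPLM-adjusted)."""

    model_form: str  # "simple" | "adjusted"
    coefficients: dict[str, float]
    r_squared: float
    p_value: float  # overall F-test of the regression
    n: int


@dataclass(frozen=True)
class SheathFractionSummary:
    """PV share of traced sheaths across ROIs at one timepoint."""

    timepoint: str
    mean_percent_pv: float
    sem_percent_pv: float
    mean_total_sheaths: float
    per_roi_percent_pv: tuple[float, ...]
    n_rois: int


def delta_plm(record: LongitudinalRecord) -> float:
    """Net change in PLM (percentage points) for one tracked axon."""
    if record.status != "present":
        raise ExcludedRecordError(
            f"axon {record.axon_id!r} has status {record.status!r}; ΔPLM undefined"
        )
    return record.plm_recovery - record.plm_baseline


def _model_records(records: Sequence[LongitudinalRecord]) -> list[LongitudinalRecord]:
    return [
        r
        for r in records
        if r.status == "present"
        and not (r.plm_baseline == 0.0 and r.plm_recovery == 0.0)
    ]


def fit_recovery_model(
    records: Sequence[LongitudinalRecord], form: str = "simple"
) -> RemyelinationModelFit:
    """Fit recovery PLM on baseline PLM by ordinary least squares.

    ``form="simple"`` fits recovery ~ 1 + baseline; ``form="adjusted"`` adds
    the baseline:ΔPLM interaction of each axon (see module docstring for the
    circularity caveat).  Lost axons and axons unmyelinated at both
    timepoints are excluded before fitting.
    """
    if form not in ("simple", "adjusted"):
        raise ValueError(f"unknown model form {form!r}")
    kept = _model_records(records)
    if not kept:
        raise ValueError("no records remain after exclusions")
    if len(kept) < 3:
        raise ValueError(f"need at least 3 usable records, got {len(kept)}")
    baseline = np.array([r.plm_baseline for r in kept])
    recovery = np.array([r.plm_recovery for r in kept])
    cols = {"(Intercept)": np.ones_like(baseline), "baseline": baseline}
    if form == "adjusted":
        dplm = recovery - baseline
        cols["baseline:dPLM"] = baseline * dplm
    X = np.column_stack(list(cols.values()))
    res = sm.OLS(recovery, X).fit()
    return RemyelinationModelFit(
        model_form=form,
        coefficients=dict(zip(cols.keys(), (float(b) for b in res.params))),
        r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue),
        n=len(kept),
    )


def identity_crossing(fit: RemyelinationModelFit) -> float:
    """PLM at which the simple fit crosses the identity line (no net change).

    Solves intercept + slope·x = x.  Below the crossing axons tend to gain
    myelin during recovery; above it they tend to lose.
    """
    if fit.model_form != "simple":
        raise ValueError("identity crossing is defined for the simple model form")
    slope = fit.coefficients["baseline"]
    intercept = fit.coefficients["(Intercept)"]
    if slope == 1.0:
        raise ZeroDivisionError(
            "slope is exactly 1: the fit is parallel to (or equals) the identity line"
        )
    return intercept / (1.0 - slope)


def tracing_error_band(control_records: Sequence[LongitudinalRecord]) -> float:
    """Half-width of the tracing-error band from control animals.

    The band is the mean of the negative ΔPLM values observed in controls
    (where no true myelin change is expected), mirrored around zero.
    Returns the non-negative half-width; zero when controls show no
    negative ΔPLM.
    """
    present = [r for r in control_records if r.status == "present"]
    if not present:
        raise ValueError("no usable control records")
    negatives = [delta_plm(r) for r in present if delta_plm(r) < 0]
    if not negatives:
        return 0.0
    return abs(float(np.mean(negatives)))


def pv_sheath_fraction(
    rois: Sequence[SheathROI], timepoint: str
) -> SheathFractionSummary:
    """Percent of traced sheaths surrounding PV axons, summarized over ROIs."""
    at_tp = [r for r in rois if r.timepoint == timepoint]
    if not at_tp:
        raise ValueError(f"no ROIs at timepoint {timepoint!r}")
    usable = []
    for r in at_tp:
        if r.n_pv_sheaths + r.n_other_sheaths == 0:
            warnings.warn(f"ROI {r.roi_id!r} has zero sheaths; excluded", RuntimeWarning)
            continue
        usable.append(r)
    if not usable:
        raise ValueError(f"all ROIs at timepoint {timepoint!r} are empty")
    fractions = np.array(
        [100.0 * r.n_pv_sheaths / (r.n_pv_sheaths + r.n_other_sheaths) for r in usable]
    )
    totals = np.array([r.n_pv_sheaths + r.n_other_sheaths for r in usable], dtype=float)
    sem = float(fractions.std(ddof=1) / np.sqrt(len(fractions))) if len(fractions) > 1 else 0.0
    return SheathFractionSummary(
        timepoint=timepoint,
        mean_percent_pv=float(fractions.mean()),
        sem_percent_pv=sem,
        mean_total_sheaths=float(totals.mean()),
        per_roi_percent_pv=tuple(float(f) for f in fractions),
        n_rois=len(usable),
    )
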