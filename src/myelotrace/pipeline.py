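"""End-to-end orchestration: simulate → coverage → diameters → model → report.

A single :class:`RunConfig` (typically loaded from YAML) drives a
deterministic run: one master seed is split into independent per-stage
streams so a single integer reproduces the whole pipeline bit-for-bit.
Stage outputs are written as TSV/JSON files under the configured output
directory together with a JSON run report recording seeds, counts and fit
summaries.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import (
    NODAL_THRESHOLD_UM,
    PLM_CAP_PERCENT,
    compute_plm,
    gaps_to_frame,
    profiles_to_frame,
)
from .diameter import axon_diameter
from .glm import d50, fit_myelination_glm, SeparationError
from .remyelination import fit_recovery_model, identity_crossing
from .synth import (
    DEFAULT_SUBTYPE_PARAMS,
    RemodelingParams,
    default_glm_coefficients,
    gen_axon_population,
    gen_intensity_profiles,
    gen_longitudinal,
)
from .traces import SUBTYPES

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    subtypes: tuple[str, ...] = ("PV", "VM", "SOM", "PO", "RBP4", "NXPH4")
    n_per_subtype: int = 60
    nodal_threshold: float = NODAL_THRESHOLD_UM
    cap_percent: float = PLM_CAP_PERCENT
    glm_reference: str = "PV"
    jitter_sd: float = 0.0
    sites_per_axon: tuple[int, int] = (2, 3)
    psf_sigma: float = 0.1
    profile_noise_sd: float = 0.05
    n_longitudinal: int = 200
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    stages: tuple[str, ...] = ("simulate", "coverage", "diameter", "glm", "longitudinal")

    def validate(self) -> None:
        unknown = set(self.subtypes) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtype labels {sorted(unknown)}")
        if self.glm_reference not in self.subtypes:
            raise ValueError(f"glm_reference {self.glm_reference!r} not among subtypes")
        if not 0 < self.nodal_threshold <= 50:
            raise ValueError("nodal_threshold outside the documented (0, 50] μm range")
        if not 0 < self.cap_percent <= 100:
            raise ValueError("cap_percent outside (0, 100]")
        if self.n_per_subtype < 0 or self.n_longitudinal < 0:
            raise ValueError("counts must be non-negative")
        bad = [s for s in self.stages if s not in ("simulate", "coverage", "diameter", "glm", "longitudinal")]
        if bad:
            raise ValueError(f"unknown stages {bad}")
        if "simulate" not in self.stages and any(
            s in self.stages for s in ("coverage", "diameter", "glm", "longitudinal")
        ):
            raise ValueError("downstream stages require the simulate stage")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    if "remodeling" in raw:
        raw["remodeling"] = RemodelingParams(**raw["remodeling"])
    for key in ("subtypes", "stages", "sites_per_axon"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order and write outputs.

    Returns the run report (also written as ``report.json``), containing per
    stage status, the seeds used, object counts, and fit summaries.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_sim, rng_site, rng_prof, rng_long = (np.random.default_rng(s) for s in streams)

    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
    }

    traces = annotations = diam_table = None
    if "simulate" in config.stages:
        params = [DEFAULT_SUBTYPE_PARAMS[s] for s in config.subtypes]
        traces, annotations, diam_table = gen_axon_population(
            params=params,
            glm_coefficients=default_glm_coefficients(),
            n_per_subtype=config.n_per_subtype,
            seed=rng_sim,
            jitter_sd=config.jitter_sd,
        )
        report["stages"]["simulate"] = {
            "status": "ok",
            "n_axons": len(traces),
            "n_internodes": len(annotations),
        }

    profiles = None
    if "coverage" in config.stages:
        by_axon: dict[str, list] = {}
        for a in annotations:
            by_axon.setdefault(a.axon_id, []).append(a)
        profiles = [
            compute_plm(
                t,
                by_axon.get(t.axon_id, []),
                cap_percent=config.cap_percent,
                nodal_threshold=config.nodal_threshold,
            )
            for t in traces
        ]
        subtype_of = {t.axon_id: t.subtype for t in traces}
        region_of = {t.axon_id: t.region for t in traces}
        prof_frame = profiles_to_frame(profiles, subtypes=subtype_of, regions=region_of)
        prof_frame.to_csv(out / "profiles.tsv", sep="\t", index=False)
        gaps_to_frame(profiles).to_csv(out / "gaps.tsv", sep="\t", index=False)
        report["stages"]["coverage"] = {
            "status": "ok",
            "n_profiles": len(profiles),
            "mean_plm": float(prof_frame["plm"].mean()),
            "proportion_myelinated": float((prof_frame["plm"] > 0).mean()),
        }

    diam_records = None
    if "diameter" in config.stages:
        lo, hi = config.sites_per_axon
        rows = []
        for r in diam_table.itertuples():
            n_sites = int(rng_site.integers(lo, hi + 1))
            site_profiles = gen_intensity_profiles(
                [r.diameter_um] * n_sites,
                psf_sigma=config.psf_sigma,
                noise_sd=config.profile_noise_sd,
                seed=rng_prof,
                myelinated=[bool(r.myelinated)] * n_sites,
            )
            rec = axon_diameter(site_profiles, axon_id=r.axon_id, subtype=r.subtype)
            rows.append(
                {
                    "axon_id": rec.axon_id,
                    "subtype": rec.subtype,
                    "mean_diameter_um": rec.mean_diameter,
                    "n_sites": len(rec.site_diameters),
                    "myelination_fraction": rec.myelination_fraction,
                }
            )
        diam_records = pd.DataFrame(rows)
        diam_records.to_csv(out / "diam.tsv", sep="\t", index=False)
        report["stages"]["diameter"] = {
            "status": "ok",
            "n_axons": len(diam_records),
            "mean_diameter_um": float(diam_records["mean_diameter_um"].mean()),
        }

    if "glm" in config.stages:
        data = [
            (r.mean_diameter_um, r.subtype, r.myelination_fraction)
            for r in diam_records.itertuples()
        ]
        weights = [float(r.n_sites) for r in diam_records.itertuples()]
        fit = fit_myelination_glm(data, reference=config.glm_reference, weights=weights)
        fit_payload = {
            "coefficients": dict(fit.coefficients),
            "standard_errors": dict(fit.standard_errors),
            "covariance": fit.covariance.tolist(),
            "terms": list(fit.terms),
            "reference": fit.reference,
            "converged": fit.converged,
            "separation_flags": sorted(fit.separation_flags),
        }
        (out / "fit.json").write_text(json.dumps(fit_payload, indent=2))
        d50_rows = []
        for s in config.subtypes:
            try:
                est = d50(fit, s)
            except (SeparationError, ZeroDivisionError):
                continue
            lo_ci, hi_ci = est.interval if est.interval else (float("nan"), float("nan"))
            d50_rows.append(
                {"subtype": s, "d50_um": est.d50, "ci_lower": lo_ci, "ci_upper": hi_ci}
            )
        pd.DataFrame(d50_rows).to_csv(out / "d50.tsv", sep="\t", index=False)
        report["stages"]["glm"] = {
            "status": "ok",
            "coefficients": dict(fit.coefficients),
            "separation_flags": sorted(fit.separation_flags),
            "d50": {row["subtype"]: row["d50_um"] for row in d50_rows},
        }

    if "longitudinal" in config.stages:
        baselines = rng_long.uniform(0.0, 99.0, size=config.n_longitudinal)
        records = gen_longitudinal(
            baselines.tolist(), remodeling=config.remodeling, seed=rng_long
        )
        simple = fit_recovery_model(records, form="simple")
        adjusted = fit_recovery_model(records, form="adjusted")
        payload = {
            "simple": asdict(simple),
            "adjusted": asdict(adjusted),
            "identity_crossing": identity_crossing(simple),
        }
        (out / "remyel.json").write_text(json.dumps(payload, indent=2))
        report["stages"]["longitudinal"] = {
            "status": "ok",
            "n_records": len(records),
            "simple_r2": simple.r_squared,
            "adjusted_r2": adjusted.r_squared,
        }

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = asdict(config)
    d["remodeling"] = asdict(config.remodeling)
    return d
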