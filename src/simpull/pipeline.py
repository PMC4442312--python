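"""End-to-end SiMPull runs: simulate/load -> detect -> traces -> steps ->
stoichiometry and colocalization, from one configuration, with a
reproducible JSON report.

Replaces ad-hoc per-experiment analysis scripts: every stage parameter lives
in :class:`RunConfig`, every stage writes its table, and the report carries
the seed and a hash of the full configuration so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .colocalization import ColocalizationResult, colocalize, register_channels
from .detection import (FieldQuantification, Spot, compare_to_control,
                        detect_spots, quantify_fields, spots_to_frame)
from .photobleaching import (SpotNearBorderError, build_step_distribution,
                             count_steps, extract_trace)
from .simulator import ImageStack, SimulationConfig, simulate_field
from .stoichiometry import co_complex_fraction_correction, infer_stoichiometry

__all__ = [
    "DetectionParams", "TraceParams", "StepFitParams", "StoichParams",
    "ColocParams", "RunConfig", "RunReport", "PipelineStageError",
    "run_pipeline",
]

log = logging.getLogger("simpull")


@dataclass(frozen=True)
class DetectionParams:
    projection_frames: int = 10
    threshold_factor: float = 5.0
    min_separation_px: int = 2


@dataclass(frozen=True)
class TraceParams:
    aperture_radius_px: float = 3.0
    annulus_radii_px: tuple[float, float] = (5.0, 7.0)
    max_traces_per_field: int | None = None


@dataclass(frozen=True)
class StepFitParams:
    max_steps: int = 5
    penalty: float = 3.0
    min_step_size: float = 0.0
    min_dwell_frames: int = 2


@dataclass(frozen=True)
class StoichParams:
    maturation_prob: float = 0.75
    n_max: int = 4
    n_restarts: int = 10
    dominant_threshold: float = 0.1


@dataclass(frozen=True)
class ColocParams:
    radius_px: float = 2.0
    offset_px: tuple[float, float] = (0.0, 0.0)
    chance_correct: bool = False


@dataclass(frozen=True)
class RunConfig:
    """One SiMPull experiment: sample (and optional control) fields plus
    the analysis parameters of every stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    control: SimulationConfig | None = None
    n_fields: int = 20
    n_control_fields: int | None = None
    seed: int = 0
    label: str = "simpull-run"
    detection: DetectionParams = field(default_factory=DetectionParams)
    trace: TraceParams = field(default_factory=TraceParams)
    steps: StepFitParams = field(default_factory=StepFitParams)
    stoichiometry: StoichParams = field(default_factory=StoichParams)
    colocalization: ColocParams = field(default_factory=ColocParams)

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunReport:
    """Self-contained summary of one pipeline run (JSON-serializable)."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def __getitem__(self, key: str):
        return self.data[key]


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _quant_dict(q: FieldQuantification) -> dict:
    return {"counts": list(q.counts), "mean": q.mean,
            "sd": None if np.isnan(q.sd) else q.sd,
            "n_areas": q.n_areas, "channel": q.channel,
            "area_um2": q.area_um2}


def _coloc_dict(r: ColocalizationResult) -> dict:
    return {
        "n_spots_a": r.n_spots_a, "n_spots_b": r.n_spots_b,
        "reference_channel": r.reference_channel,
        "n_matched": r.n_matched, "percentage": r.percentage,
        "radius_px": r.radius_px,
        "per_field_percent": list(r.per_field_percent),
        "mean_percent": r.mean_percent,
        "sd_percent": None if np.isnan(r.sd_percent) else r.sd_percent,
        "n_fields": r.n_fields,
        "expected_chance_percent": r.expected_chance_percent,
        "empty_channel": r.empty_channel,
    }


def _detect_field(stacks: dict[str, ImageStack], params: DetectionParams,
                  field: int) -> dict[str, list[Spot]]:
    return {c: detect_spots(stacks[c],
                            projection_frames=params.projection_frames,
                            threshold_factor=params.threshold_factor,
                            min_separation_px=params.min_separation_px,
                            field=field)
            for c in stacks}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute all configured stages; returns (and optionally persists) the
    run report. Any stage failure raises :class:`PipelineStageError` tagged
    with the stage name."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "label": config.label, "version": __version__, "seed": config.seed,
        "config_hash": config_hash(config), "config": asdict(config),
    }
    root_ss = np.random.SeedSequence(config.seed)
    ss_sample, ss_control = root_ss.spawn(2)
    sim = config.simulation
    channels = sim.channel_labels
    two_channel = len(channels) == 2

    # ---- per-field: simulate -> detect -> traces (one stack in memory)
    bait = channels[0]
    spots: dict[str, list[list[Spot]]] = {c: [] for c in channels}
    fits: list = []
    fit_rows: list[dict] = []
    n_border = 0
    unbleached: dict[str, list[float]] = {c: [] for c in channels}
    field_seeds = ss_sample.spawn(config.n_fields)
    for i in range(config.n_fields):
        stage = "simulate"
        try:
            stacks, truth = simulate_field(
                sim, rng=np.random.default_rng(field_seeds[i]))
            for c in channels:
                unbleached[c].append(truth.fraction_unbleached(c))
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e
        stage = "detect"
        try:
            field_spots = _detect_field(stacks, config.detection, i)
            for c in channels:
                spots[c].append(field_spots[c])
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e
        stage = "steps"
        try:
            bait_spots = field_spots[bait]
            if config.trace.max_traces_per_field is not None:
                bait_spots = bait_spots[:config.trace.max_traces_per_field]
            for s in bait_spots:
                try:
                    tr = extract_trace(
                        stacks[bait], s,
                        aperture_radius_px=config.trace.aperture_radius_px,
                        annulus_radii_px=config.trace.annulus_radii_px)
                except SpotNearBorderError:
                    n_border += 1
                    continue
                fit = count_steps(tr, max_steps=config.steps.max_steps,
                                  penalty=config.steps.penalty,
                                  min_step_size=config.steps.min_step_size,
                                  min_dwell_frames=config.steps.min_dwell_frames)
                fits.append(fit)
                fit_rows.append({
                    "field": i, "x_px": s.x_px, "y_px": s.y_px,
                    "n_steps": fit.n_steps, "accepted": fit.accepted,
                    "reason": fit.rejection_reason.value,
                    "rss": fit.rss, "noise_sd": fit.noise_sd,
                    "step_frames": ";".join(str(f) for f in fit.step_frames)})
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e
        del stacks  # free the field's image data before the next one
    report["fraction_unbleached"] = {
        c: float(np.mean(v)) for c, v in unbleached.items()}

    stage = "detect"
    try:
        area = sim.area_um2
        quants = {c: quantify_fields(spots[c], field_area_um2=area, channel=c)
                  for c in channels}
        report["quantification"] = {c: _quant_dict(q) for c, q in quants.items()}
        report["n_spots"] = {c: sum(len(f) for f in spots[c]) for c in channels}
        if config.control is not None:
            n_ctrl = config.n_control_fields or config.n_fields
            ctrl_ch = channels[0]
            ctrl_fields = []
            for child in ss_control.spawn(n_ctrl):
                cstacks, _ = simulate_field(config.control,
                                            rng=np.random.default_rng(child))
                ctrl_fields.append(_detect_field(
                    cstacks, config.detection, len(ctrl_fields))[ctrl_ch])
                del cstacks
            cq = quantify_fields(ctrl_fields,
                                 field_area_um2=config.control.area_um2,
                                 channel=ctrl_ch)
            report["control_quantification"] = _quant_dict(cq)
            enr = compare_to_control(quants[ctrl_ch], cq)
            report["specificity"] = {
                "ratio": enr.ratio, "passes_specificity": enr.passes_specificity,
                "threshold": enr.threshold, "control_floored": enr.control_floored}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e
    log.info("detect: %s spots", report["n_spots"])
    if out is not None:
        all_spots = [s for c in channels for f in spots[c] for s in f]
        spots_to_frame(all_spots).to_csv(out / "spots.csv", index=False)

    stage = "steps"
    try:
        step_dist = build_step_distribution(fits) if fits else None
        report["step_distribution"] = None if step_dist is None else {
            "counts": {str(k): v for k, v in step_dist.counts.items()},
            "total_accepted": step_dist.total_accepted,
            "rejected_by_reason": step_dist.rejected_by_reason,
            "n_border_rejected": n_border}
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e
    if out is not None and fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "step_fits.csv", index=False)

    # ---- stoichiometry -------------------------------------------------
    stage = "stoichiometry"
    try:
        report["stoichiometry"] = None
        report["stoichiometry_raw"] = None
        if step_dist is not None and step_dist.total_accepted > 0:
            sp = config.stoichiometry
            est = infer_stoichiometry(
                step_dist, m=sp.maturation_prob, n_max=sp.n_max,
                n_restarts=sp.n_restarts, seed=config.seed,
                dominant_threshold=sp.dominant_threshold)
            raw = infer_stoichiometry(
                step_dist, m=1.0, n_max=sp.n_max, n_restarts=sp.n_restarts,
                seed=config.seed, dominant_threshold=sp.dominant_threshold)
            report["stoichiometry"] = _stoich_dict(est)
            report["stoichiometry_raw"] = _stoich_dict(raw)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    # ---- colocalization ------------------------------------------------
    stage = "colocalization"
    try:
        report["colocalization"] = None
        if two_channel:
            cp = config.colocalization
            fields_a = spots[channels[0]]
            fields_b = [register_channels(f, cp.offset_px)
                        for f in spots[channels[1]]]
            res = colocalize(fields_a, fields_b, radius_px=cp.radius_px,
                             field_area_px2=float(sim.field_height_px
                                                  * sim.field_width_px),
                             channel_a=channels[0], channel_b=channels[1])
            d = _coloc_dict(res)
            if cp.chance_correct and res.expected_chance_percent is not None:
                d["chance_corrected_mean_percent"] = (
                    res.mean_percent - res.expected_chance_percent)
            m_partner = sim.channel(channels[1]).maturation_prob
            corr = co_complex_fraction_correction(
                min(res.mean_percent / 100.0, 1.0), m_partner)
            d["dark_corrected_fraction"] = corr.corrected
            d["dark_correction_capped"] = corr.capped
            report["colocalization"] = d
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError(stage, e) from e

    rep = RunReport(report)
    if out is not None:
        rep.save(out / "report.json")
    return rep


def _stoich_dict(est) -> dict:
    return {"weights": {str(k): v for k, v in est.weights.items()},
            "call": est.call, "maturation_prob": est.maturation_prob,
            "n_max": est.n_max, "log_likelihood": est.log_likelihood,
            "predicted": {str(k): v for k, v in est.predicted.items()},
            "observed": {str(k): v for k, v in est.observed.items()}}
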