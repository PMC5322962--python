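"""Experiment orchestration: discretization study, starting-phase sweep,
dose-engine variants, fixture generation, and report output.

Each experiment follows the same pattern: build (or load) segment doses for
one arc, accumulate them over a breathing trajectory, extract the coronal
detector-plane ROI, and compare planes by gamma passing rates (total / CTV /
ITV) and SDD.  All randomness is seeded through the config; two runs with
identical configs produce identical reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accumulate import AccumulationStats, CoursePlan, accumulate_4d, accumulate_course
from .delivery import ArcSpec, SegmentSchedule, discretize_arc
from .engine import BeamSpec, SegmentDoseSet, compute_segment_doses, import_segment_doses
from .gamma import (
    GammaCriteria,
    RoiMask2D,
    extract_coronal_plane,
    full_roi,
    gamma_index,
    passing_rate,
    rect_roi,
    sdd,
)
from .grid import DoseGrid, DosePlane, read_plane, write_grid, write_plane
from .motion import (
    SCENARIOS,
    ScenarioSpec,
    Trajectory,
    itv_half_extents,
    make_trajectory,
    shift_start_phase,
    write_trajectory,
)
from .phantom import PhantomModel, build_phantom

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for all experiments.

    ``delta_alpha_levels`` are the arc discretization levels (deg) under
    study; ``ground_truth_level`` designates the level whose dynamic result
    serves as ground truth when no measurement import is configured.
    """

    scenarios: tuple[str, ...] = ("1b", "1d", "2b")
    delta_alpha_levels: tuple[float, ...] = (2.3, 5.0, 10.0, 150.0)
    ground_truth_level: float = 2.3
    arc: ArcSpec = field(default_factory=ArcSpec)
    gamma: GammaCriteria = field(default_factory=GammaCriteria)
    seed: int = 1
    grid_spacing: float = 2.5        # mm, 3D dose grid
    plane_spacing: float = 2.5       # mm, comparison plane
    roi_size: float = 110.0          # mm, detector-sized ROI edge
    dt: float = 0.04                 # s, accumulation sub-step
    phase_step: float = 0.25         # s, phase-sweep resolution
    phase_max: float = 10.0          # s, phase-sweep upper bound
    aperture_margin: float = 5.0     # mm, field margin beyond the ITV
    modulation: float = 0.7          # MLC-like lateral window modulation
    sweeps: int = 3                  # aperture sweeps across the arc
    phantom_config: dict | None = None

    def phantom(self) -> PhantomModel:
        return build_phantom(self.phantom_config)

    def scenario_spec(self, label: str) -> ScenarioSpec:
        if label not in SCENARIOS:
            raise KeyError(f"unknown scenario {label!r}; known: {sorted(SCENARIOS)}")
        spec = SCENARIOS[label]
        if spec.kind == "irregular":
            # derive the scenario stream from the config seed, reproducibly
            spec = replace(spec, seed=self.seed * 1000 + (spec.seed or 0))
        return spec

    def beam_for(self, spec: ScenarioSpec) -> BeamSpec:
        itv = itv_half_extents(spec)
        lateral = max(itv[1], itv[2]) + self.aperture_margin
        return BeamSpec(aperture=(float(itv[0] + self.aperture_margin), float(lateral)),
                        modulation=self.modulation, sweeps=self.sweeps)

    def trajectory_for(self, spec: ScenarioSpec, margin: float | None = None
                       ) -> Trajectory:
        extra = self.phase_max + 2.0 * spec.period if margin is None else margin
        return make_trajectory(spec, self.arc.beam_on_time + extra)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read the structured YAML config (sections phantom / arc / motion /
    gamma / experiment)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    kw: dict = {}
    if "arc" in raw:
        kw["arc"] = ArcSpec(**raw["arc"])
    if "gamma" in raw:
        kw["gamma"] = GammaCriteria(**raw["gamma"])
    if "phantom" in raw:
        kw["phantom_config"] = raw["phantom"]
    exp = raw.get("experiment", {})
    for key in ("scenarios", "delta_alpha_levels"):
        if key in exp:
            kw[key] = tuple(exp.pop(key))
    kw.update(exp)
    return ExperimentConfig(**kw)


# ---------------------------------------------------------------------------
# Simulation building blocks
# ---------------------------------------------------------------------------

def simulate_arc(cfg: ExperimentConfig, spec: ScenarioSpec, delta_alpha: float,
                 traj: Trajectory | None = None, *,
                 doses: SegmentDoseSet | None = None,
                 density: DoseGrid | None = None,
                 stats: AccumulationStats | None = None
                 ) -> tuple[DosePlane, DosePlane, SegmentDoseSet]:
    """One accumulation run: returns (static planned plane, dynamic simulated
    plane, segment dose set) for a scenario at one discretization level."""
    phantom = cfg.phantom()
    schedule = discretize_arc(cfg.arc, delta_alpha)
    if doses is None:
        doses = compute_segment_doses(
            phantom, schedule, cfg.beam_for(spec),
            spacing=cfg.grid_spacing, density=density,
        )
    if traj is None:
        traj = cfg.trajectory_for(spec)
    static = doses.summed()
    dynamic = accumulate_4d(doses, schedule, traj, cfg.dt, stats=stats)
    p_static = extract_coronal_plane(
        static, phantom.detector_plane_ap, cfg.roi_size, cfg.plane_spacing,
        provenance="planned")
    p_dyn = extract_coronal_plane(
        dynamic, phantom.detector_plane_ap, cfg.roi_size, cfg.plane_spacing,
        provenance="simulated")
    return p_static, p_dyn, doses


def scenario_rois(cfg: ExperimentConfig, spec: ScenarioSpec, plane: DosePlane
                  ) -> dict[str, RoiMask2D]:
    """Total / ITV / CTV masks on the comparison plane (coronal projections
    of the 3D structures; CTV inside ITV inside the measurement area)."""
    itv = itv_half_extents(spec)
    ctv = rect_roi(plane, (10.0, 10.0), label="CTV")
    itv_m = rect_roi(plane, (float(itv[0]), float(max(itv[2], 10.0))), label="ITV")
    itv_m = RoiMask2D(itv_m.mask | ctv.mask, label="ITV")
    return {"total": full_roi(plane), "ITV": itv_m, "CTV": ctv}


def _compare(reference: DosePlane, evaluated: DosePlane,
             rois: dict[str, RoiMask2D], criteria: GammaCriteria
             ) -> list[dict]:
    """Gamma rates per ROI from a single gamma computation, plus SDD."""
    res = gamma_index(reference, evaluated, criteria)
    rows = []
    for name, roi in rois.items():
        rate_int, rate = passing_rate(res, None if name == "total" else roi)
        rows.append({
            "roi": name,
            "passing_rate": rate,
            "passing_rate_pct": rate_int,
            "sdd": sdd(reference, evaluated, res.evaluated_mask & roi.mask),
        })
    return rows


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_discretization_study(cfg: ExperimentConfig,
                             ground_truth_planes: dict[str, DosePlane] | None = None
                             ) -> pd.DataFrame:
    """Arc-discretization study.

    For every scenario and discretization level, the simulated
    motion-affected plane is compared (a) to the static planned plane — the
    simulated motion effect — and (b) to a designated ground-truth dynamic
    plane (an imported measurement, or by default the finest-level
    simulation).  Rows: scenario x level x comparison x ROI.
    """
    if len(cfg.delta_alpha_levels) < 2:
        raise ValueError("the discretization study needs at least two levels")
    rows = []
    for label in cfg.scenarios:
        spec = cfg.scenario_spec(label)
        traj = cfg.trajectory_for(spec)
        truth: DosePlane | None = None
        if ground_truth_planes and label in ground_truth_planes:
            truth = ground_truth_planes[label]
        results: dict[float, tuple[DosePlane, DosePlane]] = {}
        for level in sorted(set(cfg.delta_alpha_levels) | {cfg.ground_truth_level}):
            p_static, p_dyn, _ = simulate_arc(cfg, spec, level, traj)
            results[level] = (p_static, p_dyn)
        if truth is None:
            truth = results[cfg.ground_truth_level][1].with_values(
                results[cfg.ground_truth_level][1].values, provenance="simulated")
            log.info("scenario %s: ground truth = simulation at %.3g deg",
                     label, cfg.ground_truth_level)
        rois = scenario_rois(cfg, spec, truth)
        for level in cfg.delta_alpha_levels:
            p_static, p_dyn = results[level]
            for comparison, ref, ev in (
                ("static-vs-dynamic", p_static, p_dyn),
                ("truth-vs-dynamic", truth, p_dyn),
            ):
                for row in _compare(ref, ev, rois, cfg.gamma):
                    rows.append({
                        "scenario": label, "delta_alpha": level,
                        "comparison": comparison, **row,
                    })
    return pd.DataFrame(rows)


def run_phase_sweep(cfg: ExperimentConfig, scenario: str,
                    delta_alpha: float | None = None, *,
                    reference_dynamic: DosePlane | None = None) -> pd.DataFrame:
    """Starting-phase sweep.

    The breathing phase at beam-on is offset by Delta-t over
    [0, ``phase_max``] s in ``phase_step`` steps.  For each offset the
    accumulated plane is compared to the static plan (ITV gamma passing
    rate — the predicted interplay effect) and to the reference dynamic
    plane at Delta-t = 0 (SDD — the synchronization error metric).
    """
    spec = cfg.scenario_spec(scenario)
    level = cfg.ground_truth_level if delta_alpha is None else delta_alpha
    traj = cfg.trajectory_for(spec)
    offsets = np.arange(0.0, cfg.phase_max + cfg.phase_step / 2.0, cfg.phase_step)
    if traj.duration < cfg.arc.beam_on_time + offsets[-1]:
        raise ValueError("trajectory too short for the requested phase sweep")

    phantom = cfg.phantom()
    schedule = discretize_arc(cfg.arc, level)
    doses = compute_segment_doses(phantom, schedule, cfg.beam_for(spec),
                                  spacing=cfg.grid_spacing)
    p_static = extract_coronal_plane(
        doses.summed(), phantom.detector_plane_ap, cfg.roi_size,
        cfg.plane_spacing, provenance="planned")
    rois = scenario_rois(cfg, spec, p_static)

    rows = []
    ref_dyn = reference_dynamic
    for off in offsets:
        traj_off = shift_start_phase(traj, float(off))
        dyn = accumulate_4d(doses, schedule, traj_off, cfg.dt)
        p_dyn = extract_coronal_plane(
            dyn, phantom.detector_plane_ap, cfg.roi_size, cfg.plane_spacing,
            provenance="simulated")
        if ref_dyn is None:   # reference generated at Delta-t = 0
            ref_dyn = p_dyn
        res = gamma_index(p_static, p_dyn, cfg.gamma)
        _, itv_rate = passing_rate(res, rois["ITV"])
        rows.append({
            "scenario": scenario, "delta_alpha": level, "delta_t": float(off),
            "itv_passing_rate": itv_rate,
            "sdd": sdd(ref_dyn, p_dyn, res.evaluated_mask),
        })
    return pd.DataFrame(rows)


def run_engine_variants(cfg: ExperimentConfig, scenario: str,
                        delta_alpha: float | None = None,
                        variants: tuple[str, ...] = ("mid-position", "per-phase")
                        ) -> pd.DataFrame:
    """Static-dose-source study.

    Variants of the segment-dose computation: ``mid-position`` rasterizes
    the phantom at the mid-respiration reference; ``per-phase`` rasterizes
    it displaced by each segment's mean displacement (the closest-breathing-
    phase analogue); ``imported:<dir>`` loads externally computed doses.
    Pairwise gamma rates between the accumulated planes are reported.
    """
    if len(variants) < 2:
        raise ValueError("engine-variant study needs at least two variants")
    spec = cfg.scenario_spec(scenario)
    level = cfg.ground_truth_level if delta_alpha is None else delta_alpha
    phantom = cfg.phantom()
    schedule = discretize_arc(cfg.arc, level)
    traj = cfg.trajectory_for(spec)
    beam = cfg.beam_for(spec)
    base_density = phantom.rasterize(spacing=cfg.grid_spacing)

    planes: dict[str, DosePlane] = {}
    for variant in variants:
        if variant == "mid-position":
            doses = compute_segment_doses(phantom, schedule, beam,
                                          density=base_density)
        elif variant == "per-phase":
            per = []
            for seg in schedule.segments:
                s_mean = traj.displacement(
                    np.linspace(seg.t_start, seg.t_stop, 9)).mean(axis=0)
                density = phantom.rasterize(base_density, shift_mm=s_mean)
                from .engine import segment_dose
                per.append(segment_dose(phantom, seg, beam, density=density,
                                        arc=schedule.arc))
            doses = SegmentDoseSet(tuple(per), schedule, source="standin-engine")
        elif variant.startswith("imported:"):
            d = sorted(Path(variant.split(":", 1)[1]).glob("*.txt"))
            doses = import_segment_doses(d, schedule)
        else:
            raise ValueError(f"unknown engine variant {variant!r}")
        dyn = accumulate_4d(doses, schedule, traj, cfg.dt)
        planes[variant] = extract_coronal_plane(
            dyn, phantom.detector_plane_ap, cfg.roi_size, cfg.plane_spacing,
            provenance="simulated")

    rois_ref = scenario_rois(cfg, spec, planes[variants[0]])
    rows = []
    for i, va in enumerate(variants):
        for vb in variants[i + 1:]:
            for row in _compare(planes[va], planes[vb], rois_ref, cfg.gamma):
                rows.append({"scenario": scenario, "delta_alpha": level,
                             "reference": va, "evaluated": vb, **row})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures and defensive measurement import
# ---------------------------------------------------------------------------

def make_fixtures(seed: int, outdir: str | Path, *, grid_spacing: float = 4.0,
                  delta_alpha: float = 5.0, dt: float = 0.04) -> dict[str, Path]:
    """Write a deterministic fixture bundle: phantom config, all scenario
    trajectories, a segment-dose set, and planned / static / dynamic planes
    for one showcase scenario (1b).  Byte-identical for identical seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(seed=seed, grid_spacing=grid_spacing, dt=dt,
                           roi_size=100.0)
    paths: dict[str, Path] = {}

    from .phantom import default_phantom_config

    p = outdir / "phantom.yaml"
    p.write_text(yaml.safe_dump({"phantom": default_phantom_config()}))
    paths["phantom"] = p

    for label in SCENARIOS:
        spec = cfg.scenario_spec(label)
        traj = cfg.trajectory_for(spec)
        tp = outdir / f"trajectory_{label}.csv"
        write_trajectory(traj, tp)
        paths[f"trajectory_{label}"] = tp

    spec = cfg.scenario_spec("1b")
    traj = cfg.trajectory_for(spec)
    p_static, p_dyn, doses = simulate_arc(cfg, spec, delta_alpha, traj)
    for k, d in enumerate(doses.doses):
        gp = outdir / f"segment_dose_{k:03d}.txt"
        write_grid(d, gp)
        paths[f"segment_dose_{k}"] = gp
    for name, plane in (("planned", p_static), ("static_meas", p_static),
                        ("dynamic_meas", p_dyn)):
        pp = outdir / f"plane_{name}.txt"
        write_plane(plane, pp)
        paths[f"plane_{name}"] = pp
    return paths


def read_measurement_plane(path: str | Path, *, spacing: float = 2.5,
                           provenance: str = "dynamic-meas") -> DosePlane:
    """Defensive reader for exported measurement dose planes.

    Accepts the package's headered ASCII format and common measurement-export
    text dialects: plain whitespace-, comma-, semicolon- or tab-separated
    matrices, with or without comment headers.  Planes without geometry
    metadata are assumed centered on the reference point at ``spacing`` mm;
    the detected dialect is logged.
    """
    path = Path(path)
    try:
        plane = read_plane(path, provenance=provenance)
        log.info("%s: headered ASCII dose-plane dialect", path.name)
        return plane
    except Exception:
        pass
    text = path.read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith(("#", "//", ";;"))]
    if not lines:
        raise ValueError(f"empty or unreadable measurement file: {path}")
    delim = None
    numeric_lines = [ln for ln in lines if any(ch.isdigit() for ch in ln)]
    probe = numeric_lines[-1] if numeric_lines else lines[0]
    for cand in (";", ",", "\t"):
        if cand in probe:
            delim = cand
            break
    rows = []
    for ln in lines:
        parts = ln.split(delim) if delim else ln.split()
        try:
            rows.append([float(x.replace(",", ".")) if delim == ";" else float(x)
                         for x in parts if x.strip()])
        except ValueError:
            continue  # tolerate stray text lines (units, labels)
    if not rows:
        raise ValueError(f"no numeric matrix found in {path}")
    width = max(len(r) for r in rows)
    rows = [r for r in rows if len(r) == width]
    values = np.array(rows, dtype=float)
    values = np.maximum(values, 0.0)
    n0, n1 = values.shape
    origin = (-spacing * (n0 - 1) / 2.0, -spacing * (n1 - 1) / 2.0)
    log.info("%s: plain-matrix dialect (delimiter=%r, %dx%d, assumed %.3g mm "
             "spacing centered on the reference point)",
             path.name, delim or "whitespace", n0, n1, spacing)
    return DosePlane(values, (spacing, spacing), origin, provenance=provenance)


def write_report(df: pd.DataFrame, out_csv: str | Path,
                 out_txt: str | Path | None = None) -> None:
    """Write a machine-readable CSV (full precision) and, optionally, a
    human-readable table with integer percents."""
    df.to_csv(out_csv, index=False)
    if out_txt is not None:
        show = df.copy()
        if "passing_rate" in show:
            show["passing_rate"] = show["passing_rate"].round().astype(int)
        Path(out_txt).write_text(show.to_string(index=False) + "\n")
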