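"""Stand-in segment dose engine and segment-dose containers.

The engine computes the dose an arc segment deposits in the (static) phantom
with a deliberately simple photon pencil model: a divergent beam from the
segment's gantry direction, exponential attenuation along the radiological
depth through the rasterized density, an erf-smoothed rectangular aperture
(Gaussian penumbra) evaluated in the beam's-eye view, and an inverse-square
factor.  There is no scatter kernel and no build-up region: depth dose is
monotone beyond the surface.  Dose is linear in MU.

A segment's dose is the MU-weighted integral over its gantry-angle interval,
sampled at a fixed angular resolution.  Because every discretization level of
the same arc integrates the same underlying angular samples, summing a
segment-dose set reproduces the undivided full-arc dose — the consistency the
angle-discretization model requires.

Externally computed doses (ASCII matrix or DICOM RT Dose) can be imported in
place of the engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import erf

from .delivery import Segment, SegmentSchedule
from .grid import DoseGrid, read_dicom_rtdose, read_grid
from .phantom import PhantomModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeamSpec:
    """Beam model parameters for the stand-in engine.

    ``aperture`` is the (SI, lateral) half-width (mm) of the rectangular
    field opening projected to the isocenter plane; ``penumbra_sigma`` the
    Gaussian penumbra width (mm); ``mu_water`` the effective linear
    attenuation coefficient of water (1/mm, ~6 MV); ``output_cal`` the dose
    per MU (Gy/MU) at the isocenter for an unattenuated beam.
    """

    aperture: tuple[float, float] = (25.0, 25.0)
    penumbra_sigma: float = 3.0
    mu_water: float = 0.0046
    output_cal: float = 0.0145
    sad: float = 1000.0
    energy: str = "6MV"
    #: MLC-like modulation: the lateral window narrows to (1 - modulation)
    #: of the full aperture and its center sweeps across the field
    #: ``sweeps`` times over the arc, as a smooth function of the arc
    #: fraction.  0 disables modulation (static open field).
    modulation: float = 0.0
    sweeps: int = 2

    def __post_init__(self):
        if self.aperture[0] <= 0 or self.aperture[1] <= 0:
            raise ValueError("aperture must be non-empty (positive half-widths)")
        if not (0.0 <= self.modulation < 1.0):
            raise ValueError("modulation must lie in [0, 1)")

    def lateral_window(self, arc_fraction: float) -> tuple[float, float]:
        """(half-width, center) of the lateral aperture window at a given
        fraction of the arc."""
        hw_u = self.aperture[1]
        w_eff = hw_u * (1.0 - self.modulation)
        center = (hw_u - w_eff) * np.sin(
            2.0 * np.pi * self.sweeps * arc_fraction)
        return w_eff, center


@dataclass(frozen=True)
class SegmentDoseSet:
    """One static dose grid per arc segment, index-aligned with a schedule."""

    doses: tuple[DoseGrid, ...]
    schedule: SegmentSchedule
    source: str = "standin-engine"     # standin-engine | imported

    def __post_init__(self):
        if len(self.doses) != len(self.schedule):
            raise ValueError(
                f"dose count {len(self.doses)} does not match schedule "
                f"segment count {len(self.schedule)}"
            )
        ref = self.doses[0]
        for k, d in enumerate(self.doses[1:], start=1):
            if not ref.compatible_with(d):
                raise ValueError(f"segment dose {k} incompatible with segment dose 0")

    def __len__(self) -> int:
        return len(self.doses)

    def summed(self) -> DoseGrid:
        """Static (no-motion) sum over all segments."""
        total = np.zeros_like(self.doses[0].values)
        for d in self.doses:
            total += d.values
        return self.doses[0].with_values(total)


# ---------------------------------------------------------------------------
# Stand-in engine
# ---------------------------------------------------------------------------

def _beam_dose_single_angle(density: DoseGrid, angle_iec: float, mu: float,
                            beam: BeamSpec, arc_fraction: float = 0.0
                            ) -> np.ndarray:
    """Dose array for one gantry direction.

    The gantry rotates about the SI axis; at 0 deg the beam enters from the
    detector-front (anterior) side and travels along +AP.  Radiological depth
    is computed in a beam-aligned frame (parallel-ray approximation for the
    depth integral; divergence is applied to the fluence and inverse-square
    terms).
    """
    a = np.deg2rad(angle_iec)
    # beam frame unit vectors in room (SI, AP, LR) coordinates:
    #   zeta: along beam; u: lateral (in axial plane); v: longitudinal (SI)
    e_zeta = np.array([0.0, np.cos(a), np.sin(a)])
    e_u = np.array([0.0, -np.sin(a), np.cos(a)])

    si = density.axis_coords(0)
    ap = density.axis_coords(1)
    lr = density.axis_coords(2)
    sp = min(density.spacing[1], density.spacing[2])

    # beam-aligned grid covering the room grid's axial bounding circle
    ap_c = 0.5 * (ap[0] + ap[-1])
    lr_c = 0.5 * (lr[0] + lr[-1])
    radius = 0.5 * float(np.hypot(ap[-1] - ap[0], lr[-1] - lr[0])) + sp
    n_t = int(np.ceil(2.0 * radius / sp)) + 1
    tcoords = np.linspace(-radius, radius, n_t)  # zeta and u axes, mm

    # room positions of beam-frame samples (axial plane only; SI is shared)
    ZETA, U = np.meshgrid(tcoords, tcoords, indexing="ij")
    ap_pos = ap_c + ZETA * e_zeta[1] + U * e_u[1]
    lr_pos = lr_c + ZETA * e_zeta[2] + U * e_u[2]
    i_ap = (ap_pos - density.origin[1]) / density.spacing[1]
    i_lr = (lr_pos - density.origin[2]) / density.spacing[2]
    coords = np.stack([i_ap.ravel(), i_lr.ravel()])

    n_si = len(si)
    rho_beam = np.empty((n_si, n_t, n_t))
    for k in range(n_si):
        rho_beam[k] = map_coordinates(
            density.values[k], coords, order=1, mode="constant", cval=1e-3
        ).reshape(n_t, n_t)

    # radiological depth: cumulative density along zeta (from the source side)
    dz = tcoords[1] - tcoords[0]
    raddepth_beam = (np.cumsum(rho_beam, axis=1) - 0.5 * rho_beam) * dz

    # map radiological depth back to the room grid
    AP_r, LR_r = np.meshgrid(ap - ap_c, lr - lr_c, indexing="ij")
    zeta_r = AP_r * e_zeta[1] + LR_r * e_zeta[2]
    u_r = AP_r * e_u[1] + LR_r * e_u[2]
    i_z = (zeta_r - tcoords[0]) / dz
    i_u = (u_r - tcoords[0]) / dz
    coords_back = np.stack([i_z.ravel(), i_u.ravel()])
    raddepth = np.empty((n_si, len(ap), len(lr)))
    for k in range(n_si):
        raddepth[k] = map_coordinates(
            raddepth_beam[k], coords_back, order=1, mode="nearest"
        ).reshape(len(ap), len(lr))
    raddepth = np.maximum(raddepth, 0.0)

    # fluence in the beam's-eye view, projected to the isocenter plane
    dist = beam.sad + zeta_r                      # source distance, axial plane
    proj = beam.sad / dist
    u_iso = u_r * proj                            # (n_ap, n_lr)
    v_iso = si[:, None, None] * proj[None, :, :]  # (n_si, n_ap, n_lr)
    s2 = np.sqrt(2.0) * beam.penumbra_sigma
    hw_v = beam.aperture[0]
    hw_u, u_c = beam.lateral_window(arc_fraction)
    f_u = 0.5 * (erf((hw_u - (u_iso - u_c)) / s2)
                 - erf((-hw_u - (u_iso - u_c)) / s2))
    f_v = 0.5 * (erf((hw_v - v_iso) / s2) - erf((-hw_v - v_iso) / s2))
    invsq = proj**2

    dose = (
        beam.output_cal * mu
        * np.exp(-beam.mu_water * raddepth)
        * f_v * (f_u * invsq)[None, :, :]
    )
    return np.maximum(dose, 0.0)


def segment_dose(phantom: PhantomModel, segment: Segment, beam: BeamSpec,
                 grid_like: DoseGrid | None = None, *, spacing: float = 2.5,
                 angular_resolution: float = 1.0,
                 density: DoseGrid | None = None,
                 arc=None) -> DoseGrid:
    """Static dose for one arc segment on the target grid.

    The segment's angle interval is integrated at ``angular_resolution``
    (midpoint samples, MU split evenly), so segment doses of any
    discretization level of the same arc sum consistently.  ``density`` may
    supply a pre-rasterized (possibly displaced) density volume.
    """
    if segment.mu <= 0:
        raise ValueError("segment MU must be positive")
    if density is None:
        density = phantom.rasterize(grid_like, spacing=spacing)
    width = segment.cum_stop - segment.cum_start
    n_sub = max(1, int(round(width / angular_resolution)))
    cum_angles = segment.cum_start + (np.arange(n_sub) + 0.5) * width / n_sub
    if arc is not None:
        angles = arc.cumulative_to_iec(cum_angles)
        fractions = cum_angles / arc.span
    else:
        angles = cum_angles
        fractions = np.zeros_like(cum_angles)
    total = np.zeros_like(density.values)
    for ang, frac in zip(np.atleast_1d(angles), np.atleast_1d(fractions)):
        total += _beam_dose_single_angle(density, float(ang),
                                         segment.mu / n_sub, beam, float(frac))
    if total.max() == 0.0:
        log.warning("segment at angles %s does not intersect the grid; dose is zero",
                    np.atleast_1d(angles))
    return density.with_values(total)


def compute_segment_doses(phantom: PhantomModel, schedule: SegmentSchedule,
                          beam: BeamSpec, grid_like: DoseGrid | None = None, *,
                          spacing: float = 2.5, angular_resolution: float = 1.0,
                          density: DoseGrid | None = None) -> SegmentDoseSet:
    """Stand-in-engine dose set for every segment of a schedule."""
    if density is None:
        density = phantom.rasterize(grid_like, spacing=spacing)
    doses = tuple(
        segment_dose(phantom, seg, beam, density=density,
                     angular_resolution=angular_resolution, arc=schedule.arc)
        for seg in schedule.segments
    )
    return SegmentDoseSet(doses=doses, schedule=schedule, source="standin-engine")


def aggregate_micro_doses(micro: SegmentDoseSet, schedule: SegmentSchedule
                          ) -> SegmentDoseSet:
    """Re-bin a finely discretized dose set onto a coarser schedule of the
    same arc (micro segments assigned by their mid-angle).  Lets one engine
    pass serve several discretization levels."""
    if micro.schedule.arc != schedule.arc:
        raise ValueError("micro dose set and schedule must share the same arc")
    edges = np.array([s.cum_stop for s in schedule.segments])
    mids = np.array([s.cum_mid for s in micro.schedule.segments])
    idx = np.searchsorted(edges - 1e-9, mids)
    idx = np.clip(idx, 0, len(schedule) - 1)
    ref = micro.doses[0]
    sums = [np.zeros_like(ref.values) for _ in range(len(schedule))]
    for k, d in zip(idx, micro.doses):
        sums[k] += d.values
    doses = tuple(ref.with_values(v) for v in sums)
    return SegmentDoseSet(doses=doses, schedule=schedule, source=micro.source)


# ---------------------------------------------------------------------------
# Import path
# ---------------------------------------------------------------------------

def _resample_to(grid: DoseGrid, ref: DoseGrid) -> DoseGrid:
    """Trilinear resampling of ``grid`` onto the frame of ``ref``."""
    si = ref.axis_coords(0)
    ap = ref.axis_coords(1)
    lr = ref.axis_coords(2)
    SI, AP, LR = np.meshgrid(si, ap, lr, indexing="ij")
    pos = np.stack([SI, AP, LR], axis=-1)
    idx = grid.position_to_index(pos)
    vals = map_coordinates(grid.values, np.moveaxis(idx, -1, 0), order=1,
                           mode="constant", cval=0.0)
    return ref.with_values(vals)


def import_segment_doses(paths: list[str | Path], schedule: SegmentSchedule
                         ) -> SegmentDoseSet:
    """Import one externally computed dose grid per segment.

    Readable formats: the package's ASCII matrix and DICOM RT Dose.  Grids
    are resampled to the first grid's frame when spacing/origin/shape differ;
    files that cannot be read raise with the offending path named.
    """
    if len(paths) != len(schedule):
        raise ValueError(
            f"{len(paths)} dose files supplied for a {len(schedule)}-segment schedule"
        )
    grids: list[DoseGrid] = []
    for p in paths:
        p = Path(p)
        try:
            if p.suffix.lower() == ".dcm":
                g = read_dicom_rtdose(p)
            else:
                g = read_grid(p)
        except Exception as exc:
            raise ValueError(f"cannot import segment dose {p}: {exc}") from exc
        grids.append(g)
    ref = grids[0]
    out = []
    for p, g in zip(paths, grids):
        if g.compatible_with(ref):
            out.append(g)
        else:
            log.warning("resampling %s onto the frame of the first dose grid", p)
            out.append(_resample_to(g, ref))
    return SegmentDoseSet(doses=tuple(out), schedule=schedule, source="imported")
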