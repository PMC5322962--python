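"""QA comparison of dose planes: gamma index, passing rates, SDD.

The comparison pipeline mirrors array-measurement QA practice: a coronal
region of interest is extracted from the 3D dose grid at the detector plane,
resampled to the measurement resolution, optionally aligned to correct small
setup shifts, and compared with a local-normalization gamma index (default
3% / 3 mm, pixels below 20% of the reference maximum excluded).

Conventions (documented because array-QA software leaves them implicit):
the dose-difference criterion is normalized by the *reference* pixel's dose
(the reference is the ground-truth distribution); the low-dose threshold is
taken on the *reference* plane's maximum; SDD is the mean of pixel-wise
squared dose differences over the evaluated mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import DoseGrid, DosePlane

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GammaCriteria:
    dose_pct: float = 3.0        # % dose-difference criterion
    dist_mm: float = 3.0         # mm distance-to-agreement criterion
    local: bool = True           # local (reference-pixel) normalization
    threshold_pct: float = 20.0  # % of reference max below which pixels are ignored

    def __post_init__(self):
        if self.dose_pct <= 0 or self.dist_mm <= 0 or self.threshold_pct <= 0:
            raise ValueError("gamma criteria must be positive")


@dataclass(frozen=True)
class GammaResult:
    """Per-pixel gamma map.  ``gamma`` is NaN outside ``evaluated_mask``;
    ``capped`` flags pixels whose search hit the radius bound (the true
    minimum could lie outside)."""

    gamma: np.ndarray
    evaluated_mask: np.ndarray
    criteria: GammaCriteria
    capped: np.ndarray

    @property
    def pass_mask(self) -> np.ndarray:
        return self.evaluated_mask & (self.gamma <= 1.0 + 1e-12)


@dataclass(frozen=True)
class RoiMask2D:
    """Boolean pixel mask with a structure label (total | CTV | ITV)."""

    mask: np.ndarray
    label: str = "total"

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def rect_roi(plane: DosePlane, half_extents: tuple[float, float],
             center: tuple[float, float] = (0.0, 0.0), label: str = "CTV"
             ) -> RoiMask2D:
    """Axis-aligned rectangular ROI (half extents mm in SI, LR) — the
    coronal projection of a box structure."""
    si = plane.axis_coords(0)
    lr = plane.axis_coords(1)
    SI, LR = np.meshgrid(si, lr, indexing="ij")
    m = (np.abs(SI - center[0]) <= half_extents[0] + 1e-9) & \
        (np.abs(LR - center[1]) <= half_extents[1] + 1e-9)
    return RoiMask2D(mask=m, label=label)


def full_roi(plane: DosePlane) -> RoiMask2D:
    return RoiMask2D(mask=np.ones(plane.shape, dtype=bool), label="total")


# ---------------------------------------------------------------------------
# Plane extraction and resampling
# ---------------------------------------------------------------------------

def extract_coronal_plane(grid: DoseGrid, plane_ap: float, roi_size: float,
                          target_spacing: float,
                          center: tuple[float, float] = (0.0, 0.0),
                          provenance: str = "simulated") -> DosePlane:
    """Extract a square coronal ROI (axes SI, LR) from a 3D grid.

    The ROI of edge length ``roi_size`` mm is centered on ``center`` (SI, LR)
    and sampled at ``target_spacing`` by tri/bilinear interpolation; the
    number of pixels per axis is ``round(roi_size / target_spacing) + 1``.
    """
    ap0 = grid.axis_coords(1)[0]
    ap1 = grid.axis_coords(1)[-1]
    if not (ap0 - 1e-9 <= plane_ap <= ap1 + 1e-9):
        raise ValueError(f"plane AP={plane_ap} mm outside grid [{ap0}, {ap1}] mm")
    n = int(round(roi_size / target_spacing)) + 1
    half = roi_size / 2.0
    si = center[0] - half + target_spacing * np.arange(n)
    lr = center[1] - half + target_spacing * np.arange(n)
    if si[0] < grid.axis_coords(0)[0] - 1e-9 or si[-1] > grid.axis_coords(0)[-1] + 1e-9 \
            or lr[0] < grid.axis_coords(2)[0] - 1e-9 or lr[-1] > grid.axis_coords(2)[-1] + 1e-9:
        raise ValueError("requested ROI exceeds the dose grid extent")
    SI, LR = np.meshgrid(si, lr, indexing="ij")
    pos = np.stack([SI, np.full_like(SI, plane_ap), LR], axis=-1)
    idx = grid.position_to_index(pos)
    vals = map_coordinates(grid.values, np.moveaxis(idx, -1, 0), order=1,
                           mode="nearest")
    return DosePlane(np.maximum(vals, 0.0), (target_spacing, target_spacing),
                     (si[0], lr[0]), provenance=provenance)


def _sample_plane_at(plane: DosePlane, si: np.ndarray, lr: np.ndarray,
                     cval: float = 0.0) -> np.ndarray:
    i = (si - plane.origin[0]) / plane.spacing[0]
    j = (lr - plane.origin[1]) / plane.spacing[1]
    return map_coordinates(plane.values, np.stack([np.ravel(i), np.ravel(j)]),
                           order=1, mode="constant", cval=cval
                           ).reshape(np.shape(i))


def align_planes(reference: DosePlane, moving: DosePlane,
                 max_shift: float = 5.0, step: float = 0.5
                 ) -> tuple[DosePlane, tuple[float, float]]:
    """Correct small in-plane setup shifts.

    Exhaustive (SI, LR) translation search over +/-``max_shift`` mm at
    ``step`` resolution minimizing the summed squared difference to the
    reference, followed by parabolic sub-step refinement.  Returns the
    shifted moving plane (resampled onto the reference grid) and the shift.
    """
    si = reference.axis_coords(0)
    lr = reference.axis_coords(1)
    SI, LR = np.meshgrid(si, lr, indexing="ij")
    if np.ptp(moving.values) < 1e-12 or np.ptp(reference.values) < 1e-12:
        warnings.warn("featureless plane(s): alignment skipped, zero shift",
                      stacklevel=2)
        shifted = DosePlane(_sample_plane_at(moving, SI, LR),
                            reference.spacing, reference.origin,
                            provenance=moving.provenance)
        return shifted, (0.0, 0.0)

    offsets = np.arange(-max_shift, max_shift + step / 2.0, step)
    ssd = np.empty((len(offsets), len(offsets)))
    for a, dsi in enumerate(offsets):
        for b, dlr in enumerate(offsets):
            vals = _sample_plane_at(moving, SI + dsi, LR + dlr, cval=np.nan)
            ok = np.isfinite(vals)
            ssd[a, b] = np.mean((vals[ok] - reference.values[ok]) ** 2)
    a0, b0 = np.unravel_index(np.argmin(ssd), ssd.shape)
    if a0 in (0, len(offsets) - 1) or b0 in (0, len(offsets) - 1):
        warnings.warn("alignment optimum on the search boundary — possible "
                      "gross misalignment", stacklevel=2)
    best = [offsets[a0], offsets[b0]]
    for axis, k in ((0, a0), (1, b0)):
        if 0 < k < len(offsets) - 1:
            if axis == 0:
                y0, y1, y2 = ssd[k - 1, b0], ssd[k, b0], ssd[k + 1, b0]
            else:
                y0, y1, y2 = ssd[a0, k - 1], ssd[a0, k], ssd[a0, k + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom > 1e-300:
                best[axis] = offsets[k] + step * 0.5 * (y0 - y2) / denom
    vals = _sample_plane_at(moving, SI + best[0], LR + best[1])
    # the aligned plane lives on the reference grid
    out = DosePlane(np.maximum(vals, 0.0), reference.spacing, reference.origin,
                    provenance=moving.provenance)
    return out, (float(best[0]), float(best[1]))


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------

def gamma_index(reference: DosePlane, evaluated: DosePlane,
                criteria: GammaCriteria = GammaCriteria(), *,
                search_factor: float = 3.0, upsample: int = 10) -> GammaResult:
    """Local-normalization 2D gamma index.

    For each reference pixel r above the dose threshold,

        gamma(r) = min over positions e of sqrt(
            (D_ev(e) - D_ref(r))^2 / (crit * D_ref(r))^2
          + |e - r|^2 / dist^2 )

    with the evaluated distribution bilinearly interpolated on a search grid
    of step ``dist / upsample`` inside a radius ``search_factor * dist``.
    Pixels whose minimum lies at the search boundary are flagged ``capped``.
    With ``criteria.local`` False, normalization uses the global reference
    maximum instead of the local reference dose.
    """
    ref = reference.values
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("reference plane is identically zero")
    mask = ref >= criteria.threshold_pct / 100.0 * ref_max
    if not np.any(mask):
        raise ValueError("no pixel exceeds the dose threshold — empty gamma mask")

    dist = criteria.dist_mm
    step = dist / upsample
    radius = search_factor * dist
    n_off = int(np.floor(radius / step))
    offs = step * np.arange(-n_off, n_off + 1)
    OSI, OLR = np.meshgrid(offs, offs, indexing="ij")
    in_disk = OSI**2 + OLR**2 <= radius**2 + 1e-9
    offsets = np.column_stack([OSI[in_disk], OLR[in_disk]])
    dist2 = (offsets[:, 0] ** 2 + offsets[:, 1] ** 2) / dist**2

    si = reference.axis_coords(0)
    lr = reference.axis_coords(1)
    SI, LR = np.meshgrid(si, lr, indexing="ij")
    r_si = SI[mask]
    r_lr = LR[mask]
    d_ref = ref[mask]
    if criteria.local:
        denom = criteria.dose_pct / 100.0 * d_ref
    else:
        denom = np.full_like(d_ref, criteria.dose_pct / 100.0 * ref_max)

    gmin2 = np.full(d_ref.shape, np.inf)
    boundary2 = np.full(d_ref.shape, np.inf)   # best over boundary ring only
    r_bound = radius - step
    for (dsi, dlr), dd2 in zip(offsets, dist2):
        vals = _sample_plane_at(evaluated, r_si + dsi, r_lr + dlr, cval=np.nan)
        g2 = (vals - d_ref) ** 2 / denom**2 + dd2
        ok = np.isfinite(g2)
        np.minimum(gmin2, np.where(ok, g2, np.inf), out=gmin2)
        if dsi**2 + dlr**2 >= r_bound**2:
            np.minimum(boundary2, np.where(ok, g2, np.inf), out=boundary2)

    gamma = np.full(ref.shape, np.nan)
    gamma[mask] = np.sqrt(gmin2)
    capped = np.zeros(ref.shape, dtype=bool)
    capped[mask] = np.isclose(gmin2, boundary2) & np.isfinite(gmin2)
    return GammaResult(gamma=gamma, evaluated_mask=mask, criteria=criteria,
                       capped=capped)


def passing_rate(result: GammaResult, roi: RoiMask2D | None = None
                 ) -> tuple[int, float]:
    """Percentage of evaluated in-ROI pixels with gamma <= 1.

    Returns ``(rounded_percent, exact_percent)`` — tables print integer
    percents, machine-readable output keeps full precision.
    """
    m = result.evaluated_mask if roi is None else (result.evaluated_mask & roi.mask)
    n = int(m.sum())
    if n == 0:
        raise ValueError(
            f"ROI {'total' if roi is None else roi.label!r} has no evaluated pixel"
        )
    exact = 100.0 * float((result.gamma[m] <= 1.0 + 1e-12).sum()) / n
    return int(round(exact)), exact


def sdd(reference: DosePlane, evaluated: DosePlane,
        mask: RoiMask2D | np.ndarray | None = None) -> float:
    """Mean pixel-wise squared dose difference (Gy^2) over a mask."""
    if not reference.compatible_with(evaluated):
        raise ValueError("SDD requires compatible planes")
    m = np.ones(reference.shape, dtype=bool) if mask is None else (
        mask.mask if isinstance(mask, RoiMask2D) else np.asarray(mask, dtype=bool))
    if not np.any(m):
        raise ValueError("empty SDD mask")
    diff = reference.values[m] - evaluated.values[m]
    return float(np.mean(diff**2))


# ---------------------------------------------------------------------------
# Detector-array emulation
# ---------------------------------------------------------------------------

def detector_chamber_centers(inner_half: float = 27.5, outer_half: float = 55.0,
                             inner_pitch: float = 2.5, outer_pitch: float = 5.0
                             ) -> np.ndarray:
    """Chamber center positions (mm) of a 2D array with a finely pitched
    inner region and a coarser outer region (11 x 11 cm overall)."""
    inner = np.arange(-inner_half, inner_half + 1e-9, inner_pitch)
    outer = np.arange(-outer_half, outer_half + 1e-9, outer_pitch)
    pts = [(a, b) for a in inner for b in inner]
    for a in outer:
        for b in outer:
            if abs(a) > inner_half + 1e-9 or abs(b) > inner_half + 1e-9:
                pts.append((a, b))
    return np.array(sorted(set(pts)))


def resample_to_detector(plane: DosePlane, *, chamber_size: float = 2.3,
                         grid_spacing: float = 2.5, half_extent: float = 55.0
                         ) -> DosePlane:
    """Emulate the measurement chain: average dose over each chamber
    footprint, then re-grid the chamber readings onto the uniform comparison
    grid by linear interpolation."""
    si = plane.axis_coords(0)
    lr = plane.axis_coords(1)
    if si[0] > -half_extent + 1e-9 or si[-1] < half_extent - 1e-9 \
            or lr[0] > -half_extent + 1e-9 or lr[-1] < half_extent - 1e-9:
        raise ValueError("plane does not cover the 11 x 11 cm detector area")
    centers = detector_chamber_centers(outer_half=half_extent)
    # midpoint-rule footprint average (unbiased for piecewise-linear dose)
    n_sub = 9
    sub = ((np.arange(n_sub) + 0.5) / n_sub - 0.5) * chamber_size
    readings = np.zeros(len(centers))
    for dsi in sub:
        for dlr in sub:
            readings += _sample_plane_at(plane, centers[:, 0] + dsi,
                                         centers[:, 1] + dlr)
    readings /= n_sub**2

    from scipy.interpolate import griddata

    n = int(round(2.0 * half_extent / grid_spacing)) + 1
    ax = -half_extent + grid_spacing * np.arange(n)
    SI, LR = np.meshgrid(ax, ax, indexing="ij")
    vals = griddata(centers, readings, (SI, LR), method="linear")
    nearest = griddata(centers, readings, (SI, LR), method="nearest")
    vals = np.where(np.isfinite(vals), vals, nearest)
    return DosePlane(np.maximum(vals, 0.0), (grid_spacing, grid_spacing),
                     (ax[0], ax[0]), provenance=plane.provenance)
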