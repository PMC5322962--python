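"""Synthetic thorax phantom: geometric inserts with mass densities.

The phantom mimics a QA motion-phantom add-on: a solid-water body housing a
low-density lung insert, a water-equivalent tumor insert (which defines the
2x2x2 cm CTV), and a bone insert.  Rasterizing the phantom onto a grid yields
a density volume used by the stand-in dose engine for radiological depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import DEFAULT_FRAME, DoseGrid

log = logging.getLogger(__name__)

#: default mass densities in g/cm^3 per insert material
DEFAULT_DENSITIES = {
    "solid-water": 1.00,
    "lung": 0.30,
    "tumor": 1.00,
    "bone": 1.85,
}

CTV_SIZE_MM = 20.0  # 2x2x2 cm clinical target volume edge length


@dataclass(frozen=True)
class Insert:
    """A geometric insert: axis-aligned ``box``, ``sphere`` or SI-axis
    ``cylinder`` with a mass density and a material label."""

    shape: str                      # box | sphere | cylinder
    center: tuple[float, float, float]   # mm, (SI, AP, LR)
    size: tuple[float, float, float]     # full extents mm (sphere: diameter)
    density: float                  # g/cm^3
    label: str

    def __post_init__(self):
        if self.shape not in ("box", "sphere", "cylinder"):
            raise ValueError(f"unknown insert shape {self.shape!r}")
        if self.density <= 0:
            raise ValueError(f"insert {self.label!r}: density must be positive")

    def contains(self, si: np.ndarray, ap: np.ndarray, lr: np.ndarray) -> np.ndarray:
        """Boolean membership for room coordinates (broadcastable, mm)."""
        c = self.center
        h = tuple(s / 2.0 for s in self.size)
        if self.shape == "box":
            return (
                (np.abs(si - c[0]) <= h[0])
                & (np.abs(ap - c[1]) <= h[1])
                & (np.abs(lr - c[2]) <= h[2])
            )
        if self.shape == "sphere":
            r = h[0]
            return (si - c[0]) ** 2 + (ap - c[1]) ** 2 + (lr - c[2]) ** 2 <= r**2
        # cylinder: axis along SI
        return (
            (np.abs(si - c[0]) <= h[0])
            & (((ap - c[1]) / max(h[1], 1e-12)) ** 2
               + ((lr - c[2]) / max(h[2], 1e-12)) ** 2 <= 1.0)
        )


@dataclass(frozen=True)
class PhantomModel:
    """Geometric phantom: ordered inserts painted over a background medium.

    Later inserts overwrite earlier ones where they overlap (tumor inside
    lung inside body), except that overlaps between inserts whose labels
    disagree and which are not in a declared containment order raise at build
    time (see :func:`build_phantom`).
    """

    bounding_box: tuple[float, float, float]     # full extents mm
    inserts: tuple[Insert, ...]
    background_density: float = DEFAULT_DENSITIES["solid-water"]
    detector_plane_ap: float = 0.0               # coronal plane position, mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def ctv_center(self) -> tuple[float, float, float]:
        for ins in self.inserts:
            if ins.label == "tumor":
                return ins.center
        return self.center

    def ctv_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the 2x2x2 cm CTV cube centered on the tumor."""
        c = np.array(self.ctv_center)
        return c - CTV_SIZE_MM / 2.0, c + CTV_SIZE_MM / 2.0

    def density_at(self, si, ap, lr) -> np.ndarray:
        si, ap, lr = np.broadcast_arrays(np.asarray(si, float),
                                         np.asarray(ap, float),
                                         np.asarray(lr, float))
        rho = np.full(si.shape, self.background_density, dtype=float)
        for ins in self.inserts:
            rho[ins.contains(si, ap, lr)] = ins.density
        return rho

    def rasterize(self, grid_like: DoseGrid | None = None, *,
                  spacing: float = 2.0, shift_mm=None,
                  supersample: int = 2) -> DoseGrid:
        """Density volume on a grid.

        Each voxel averages ``supersample**3`` sub-voxel density samples, so
        voxels straddling an insert boundary carry partial-volume densities
        and insert volumes are resolution-consistent.  ``shift_mm`` rigidly
        displaces the phantom (SI, AP, LR) before rasterization — used by
        the per-phase dose-engine variant."""
        if grid_like is None:
            n = [int(np.ceil(b / spacing)) + 1 for b in self.bounding_box]
            origin = tuple(self.center[a] - (n[a] - 1) * spacing / 2.0 for a in range(3))
            si = origin[0] + spacing * np.arange(n[0])
            ap = origin[1] + spacing * np.arange(n[1])
            lr = origin[2] + spacing * np.arange(n[2])
            sp = (spacing, spacing, spacing)
            frame = DEFAULT_FRAME
        else:
            si = grid_like.axis_coords(0)
            ap = grid_like.axis_coords(1)
            lr = grid_like.axis_coords(2)
            sp = grid_like.spacing
            origin = grid_like.origin
            frame = grid_like.frame
        s = np.zeros(3) if shift_mm is None else np.asarray(shift_mm, float)
        ss = max(1, int(supersample))
        sub = (np.arange(ss) + 0.5) / ss - 0.5     # sub-voxel offsets, voxel units
        rho = np.zeros((len(si), len(ap), len(lr)))
        for o0 in sub:
            for o1 in sub:
                for o2 in sub:
                    SI, AP, LR = np.meshgrid(
                        si - s[0] + o0 * sp[0], ap - s[1] + o1 * sp[1],
                        lr - s[2] + o2 * sp[2], indexing="ij")
                    rho += self.density_at(SI, AP, LR)
        rho /= ss**3
        return DoseGrid(rho, sp, origin, frame=frame)


def default_phantom_config() -> dict:
    """Default insert geometry: lung box containing a tumor cube, with a
    bone rod posterior to the lung."""
    return {
        "bounding_box": [110.0, 110.0, 110.0],
        "background": "solid-water",
        "detector_plane_ap": 0.0,
        "inserts": [
            {"shape": "box", "label": "lung", "center": [0.0, 0.0, 0.0],
             "size": [80.0, 70.0, 80.0]},
            {"shape": "box", "label": "tumor", "center": [0.0, 0.0, 0.0],
             "size": [30.0, 30.0, 30.0]},
            {"shape": "cylinder", "label": "bone", "center": [0.0, 45.0, 0.0],
             "size": [90.0, 12.0, 12.0]},
        ],
    }


_CONTAINMENT_OK = {("lung", "tumor"), ("solid-water", "lung"),
                   ("solid-water", "bone"), ("solid-water", "tumor")}


def build_phantom(config: dict | None = None) -> PhantomModel:
    """Build a :class:`PhantomModel` from a config mapping.

    An empty insert list yields a uniform water phantom.  Overlapping inserts
    whose labels conflict (neither contains the other by declared order)
    raise; a tumor insert not fully inside a lung insert is allowed but
    logged as a warning.
    """
    cfg = dict(default_phantom_config() if config is None else config)
    bbox = tuple(float(b) for b in cfg.get("bounding_box", [110.0, 110.0, 110.0]))
    densities = {**DEFAULT_DENSITIES, **cfg.get("densities", {})}
    inserts = []
    for spec in cfg.get("inserts", []):
        label = spec["label"]
        ins = Insert(
            shape=spec.get("shape", "box"),
            center=tuple(float(c) for c in spec.get("center", (0, 0, 0))),
            size=tuple(float(s) for s in np.broadcast_to(
                np.asarray(spec.get("size", 20.0), float), (3,))),
            density=float(spec.get("density", densities.get(label, 1.0))),
            label=label,
        )
        half = np.array(ins.size) / 2.0
        lo = np.array(ins.center) - half
        hi = np.array(ins.center) + half
        if np.any(lo < -np.array(bbox) / 2.0 - 1e-9) or np.any(hi > np.array(bbox) / 2.0 + 1e-9):
            raise ValueError(f"insert {label!r} does not fit inside the phantom body {bbox}")
        inserts.append(ins)

    _check_overlaps(inserts)
    _check_tumor_in_lung(inserts)

    return PhantomModel(
        bounding_box=bbox,
        inserts=tuple(inserts),
        background_density=densities.get(cfg.get("background", "solid-water"), 1.0),
        detector_plane_ap=float(cfg.get("detector_plane_ap", 0.0)),
    )


def _aabb(ins: Insert):
    half = np.array(ins.size) / 2.0
    return np.array(ins.center) - half, np.array(ins.center) + half


def _check_overlaps(inserts: list[Insert]) -> None:
    for i in range(len(inserts)):
        for j in range(i + 1, len(inserts)):
            a, b = inserts[i], inserts[j]
            if a.label == b.label:
                continue
            alo, ahi = _aabb(a)
            blo, bhi = _aabb(b)
            overlap = np.all(ahi > blo + 1e-9) and np.all(bhi > alo + 1e-9)
            if overlap and (a.label, b.label) not in _CONTAINMENT_OK \
                    and (b.label, a.label) not in _CONTAINMENT_OK:
                raise ValueError(
                    f"inserts {a.label!r} and {b.label!r} overlap with conflicting labels"
                )


def _check_tumor_in_lung(inserts: list[Insert]) -> None:
    tumors = [i for i in inserts if i.label == "tumor"]
    lungs = [i for i in inserts if i.label == "lung"]
    if not tumors or not lungs:
        return
    # brute-force voxel containment test on the tumor bounding box
    for t in tumors:
        lo, hi = _aabb(t)
        pts = np.stack(np.meshgrid(*[np.linspace(l, h, 7) for l, h in zip(lo, hi)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        in_t = np.zeros(len(pts), dtype=bool)
        in_any_lung = np.zeros(len(pts), dtype=bool)
        in_t = t.contains(pts[:, 0], pts[:, 1], pts[:, 2])
        for lg in lungs:
            in_any_lung |= lg.contains(pts[:, 0], pts[:, 1], pts[:, 2])
        if np.any(in_t & ~in_any_lung):
            log.warning(
                "tumor insert at %s extends outside every lung insert; "
                "phantom built anyway", t.center,
            )
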