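"""Regular dose grids and planes.

Room coordinate convention: millimetres, isocenter at the origin, axes ordered
(SI, AP, LR).  3D grid values are indexed ``values[i_si, i_ap, i_lr]``; a
coronal plane (fixed AP position) is indexed ``values[i_si, i_lr]``.  Voxel
indices are 0-based and positions refer to voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

AXES_3D = ("SI", "AP", "LR")
DEFAULT_FRAME = "SI-AP-LR"


def _as_tuple(x, n: int) -> tuple[float, ...]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,))
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class DoseGrid:
    """Scalar field (dose in Gy, or mass density when used as a phantom map)
    on a regular 3D grid.

    Parameters
    ----------
    values
        Non-negative voxel values, shape ``(n_si, n_ap, n_lr)``.
    spacing
        Per-axis voxel size in mm (scalar broadcasts to all axes).
    origin
        Room position (mm) of the center of voxel ``(0, 0, 0)``.
    frame
        Axis-order / orientation tag; arithmetic requires matching frames.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = DEFAULT_FRAME

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise ValueError(f"DoseGrid values must be 3D, got ndim={vals.ndim}")
        if np.any(vals < 0):
            raise ValueError("dose/density values must be non-negative")
        sp = _as_tuple(self.spacing, 3)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple(self.origin, 3))

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Room coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def position_to_index(self, pos_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index for room positions, shape (..., 3)."""
        pos = np.asarray(pos_mm, dtype=float)
        return (pos - np.array(self.origin)) / np.array(self.spacing)

    def compatible_with(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and self.frame == other.frame
        )

    def require_compatible(self, other: "DoseGrid") -> None:
        if not self.compatible_with(other):
            raise ValueError(
                "incompatible grids: "
                f"shape {self.shape} vs {other.shape}, spacing {self.spacing} vs "
                f"{other.spacing}, origin {self.origin} vs {other.origin}, "
                f"frame {self.frame!r} vs {other.frame!r}"
            )

    # -- arithmetic --------------------------------------------------------
    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        self.require_compatible(other)
        return self.with_values(self.values + other.values)

    def __mul__(self, scalar: float) -> "DoseGrid":
        return self.with_values(self.values * float(scalar))

    __rmul__ = __mul__

    def integral(self) -> float:
        """Sum of voxel values (dose-volume surrogate on a fixed grid)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class DosePlane:
    """2D dose distribution on a regular coronal grid (axes SI, LR).

    ``provenance`` tags the origin of the plane: ``planned``, ``static-meas``,
    ``dynamic-meas`` or ``simulated``.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: str = "simulated"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"DosePlane values must be 2D, got ndim={vals.ndim}")
        if np.any(vals < 0):
            raise ValueError("dose values must be non-negative")
        sp = _as_tuple(self.spacing, 2)
        if any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", _as_tuple(self.origin, 2))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def compatible_with(self, other: "DosePlane") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, provenance: str | None = None) -> "DosePlane":
        out = replace(self, values=np.asarray(values, dtype=float))
        if provenance is not None:
            out = replace(out, provenance=provenance)
        return out


# ---------------------------------------------------------------------------
# ASCII exchange format: 4-line header (shape, spacing mm, origin mm, unit),
# then the matrix.  3D grids are written as n_si blocks of (n_ap x n_lr).
# ---------------------------------------------------------------------------

def write_grid(grid: DoseGrid, path: str | Path, unit: str = "Gy") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# shape: " + " ".join(str(n) for n in grid.shape) + "\n")
        fh.write("# spacing_mm: " + " ".join(repr(s) for s in grid.spacing) + "\n")
        fh.write("# origin_mm: " + " ".join(repr(o) for o in grid.origin) + "\n")
        fh.write(f"# unit: {unit}\n")
        flat = grid.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
        np.savetxt(fh, flat, fmt="%.9e")


def read_grid(path: str | Path, frame: str = DEFAULT_FRAME) -> DoseGrid:
    path = Path(path)
    header: dict[str, list[str]] = {}
    with path.open() as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"empty dose file: {path}")
    data_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            key, _, rest = ln[1:].partition(":")
            header[key.strip().rstrip(":")] = rest.split()
            data_start = i + 1
        else:
            break
    for key in ("shape", "spacing_mm", "origin_mm"):
        if key not in header:
            raise ValueError(f"{path}: missing header line '{key}'")
    shape = tuple(int(n) for n in header["shape"])
    spacing = tuple(float(s) for s in header["spacing_mm"])
    origin = tuple(float(o) for o in header["origin_mm"])
    data = np.loadtxt(lines[data_start:], ndmin=2)
    if len(shape) == 3:
        values = data.reshape(shape)
        return DoseGrid(values, spacing, origin, frame=frame)
    raise ValueError(f"{path}: expected 3D shape header, got {shape}")


def write_plane(plane: DosePlane, path: str | Path, unit: str = "Gy") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# shape: " + " ".join(str(n) for n in plane.shape) + "\n")
        fh.write("# spacing_mm: " + " ".join(repr(s) for s in plane.spacing) + "\n")
        fh.write("# origin_mm: " + " ".join(repr(o) for o in plane.origin) + "\n")
        fh.write(f"# unit: {unit}\n")
        np.savetxt(fh, plane.values, fmt="%.9e")


def read_plane(path: str | Path, provenance: str = "simulated") -> DosePlane:
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"empty dose-plane file: {path}")
    header: dict[str, list[str]] = {}
    data_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            key, _, rest = ln[1:].partition(":")
            header[key.strip().rstrip(":")] = rest.split()
            data_start = i + 1
        else:
            break
    if "shape" in header and len(header["shape"]) == 3:
        raise ValueError(f"{path}: 3D grid file passed to read_plane")
    data = np.loadtxt(lines[data_start:], ndmin=2)
    spacing = tuple(float(s) for s in header.get("spacing_mm", ["1", "1"]))
    origin = tuple(float(o) for o in header.get("origin_mm", ["0", "0"]))
    return DosePlane(data, spacing, origin, provenance=provenance)


def read_dicom_rtdose(path: str | Path, frame: str = DEFAULT_FRAME) -> DoseGrid:
    """Read a DICOM RT Dose file (grid scaling applied).

    DICOM stores the dose cube as (frames, rows, columns) with patient axis
    conventions; the cube is returned as-is under the package's axis-order
    tag — callers importing clinical data are responsible for declaring the
    frame mapping.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    scale = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scale
    dz = float(ds.GridFrameOffsetVector[1] - ds.GridFrameOffsetVector[0]) \
        if len(getattr(ds, "GridFrameOffsetVector", [])) > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (dz, dy, dx), origin, frame=frame)


def bilinear_sample_plane(plane: DosePlane, pos_si: np.ndarray, pos_lr: np.ndarray,
                          cval: float = np.nan) -> np.ndarray:
    """Bilinear interpolation of a plane at room positions (mm)."""
    from scipy.ndimage import map_coordinates

    i = (np.asarray(pos_si, float) - plane.origin[0]) / plane.spacing[0]
    j = (np.asarray(pos_lr, float) - plane.origin[1]) / plane.spacing[1]
    return map_coordinates(plane.values, np.stack([i, j]), order=1,
                           mode="constant", cval=cval)


def translate_trilinear(values: np.ndarray, shift_idx: np.ndarray) -> np.ndarray:
    """Sample ``values`` at index positions ``x + shift_idx`` (trilinear, zero
    outside the array) — out[x] = values[x + shift].

    Implemented as an 8-corner weighted sum of integer-shifted views, which is
    exact trilinear interpolation for a pure translation and avoids per-call
    scipy overhead in the accumulation inner loop.
    """
    shift = np.asarray(shift_idx, dtype=float)
    lo = np.floor(shift).astype(int)
    frac = shift - lo
    out = np.zeros_like(values, dtype=float)
    for corner in range(8):
        bits = [(corner >> b) & 1 for b in range(3)]
        w = 1.0
        for b in range(3):
            w *= frac[b] if bits[b] else (1.0 - frac[b])
        if w == 0.0:
            continue
        offset = lo + np.array(bits)
        out += w * _integer_shifted(values, offset)
    return out


def _integer_shifted(values: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """View of values[x + offset] with zero padding outside, offset integer."""
    ndim = values.ndim
    src = []
    dst = []
    for ax in range(ndim):
        n = values.shape[ax]
        o = int(offset[ax])
        if o >= n or o <= -n:
            return np.zeros_like(values, dtype=float)
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out = np.zeros_like(values, dtype=float)
    out[tuple(dst)] = values[tuple(src)]
    return out
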