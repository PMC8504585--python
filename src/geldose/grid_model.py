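"""Voxel-grid containers and file I/O shared by every analysis stage.

Conventions
-----------
* Indices are 0-based and a voxel's world coordinate is the position of its
  **center** (center-based coordinates are what makes distance-to-agreement
  searches geometrically honest).
* Grids are axis-aligned: no rotation matrix, anisotropic spacing allowed.
* Units: distances in mm, times in seconds, dose in Gy, R2 in s^-1.
  Unit conversion happens only at I/O boundaries.

Interchange formats: NIfTI (.nii/.nii.gz) with a JSON sidecar for the
normalization flags, ``.npz`` for self-contained fixtures, and DICOM RT-Dose
as a read-only import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "DoseGrid",
    "MultiEchoImage",
    "R2Map",
    "world_to_index",
    "index_to_world",
    "read_grid",
    "write_grid",
    "read_multiecho",
    "write_multiecho",
    "save_r2_map",
    "load_r2_map",
]


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel lattice: shape, spacing (mm) and origin (mm).

    ``origin`` is the world position of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("GridGeometry requires 3-component shape/spacing/origin")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape components must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        if any(not np.isfinite(o) for o in origin):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- coordinate helpers -------------------------------------------------
    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (X, Y, Z) world-coordinate arrays of every voxel center."""
        ax = [self.axis_coordinates(k) for k in range(3)]
        return np.meshgrid(ax[0], ax[1], ax[2], indexing="ij", sparse=False)

    def contains_index(self, index: Sequence[float]) -> bool:
        return all(-0.5 <= index[k] <= self.shape[k] - 0.5 for k in range(3))

    def nearest_voxel(self, point: Sequence[float]) -> tuple[int, int, int]:
        idx = np.rint(world_to_index(self, point)).astype(int)
        if not self.contains_index(idx):
            raise ValueError(f"point {tuple(point)} lies outside the grid")
        return tuple(int(i) for i in idx)


def world_to_index(geometry: GridGeometry, point: Sequence[float]) -> np.ndarray:
    """Continuous voxel index of a world point: ``(point - origin) / spacing``.

    Points outside the grid map to out-of-range indices; callers decide how to
    treat them.
    """
    p = np.asarray(point, dtype=float)
    return (p - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)


def index_to_world(geometry: GridGeometry, index: Sequence[float]) -> np.ndarray:
    """World coordinate of a (possibly fractional) voxel index."""
    i = np.asarray(index, dtype=float)
    return np.asarray(geometry.origin) + i * np.asarray(geometry.spacing)


@dataclass
class DoseGrid:
    """A 3D absorbed-dose distribution on a :class:`GridGeometry`.

    ``values`` are Gy, or dimensionless when ``normalized`` is set, in which
    case ``normalization_value`` records the Gy dose the grid was divided by.
    """

    geometry: GridGeometry
    values: np.ndarray
    normalized: bool = False
    normalization_value: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.geometry.shape):
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        if self.normalization_value is not None:
            self.normalization_value = float(self.normalization_value)


@dataclass
class MultiEchoImage:
    """4D multi-spin-echo magnitude image: 3 spatial axes x echoes."""

    geometry: GridGeometry
    echo_times: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray  # (nx, ny, nz, n_echoes), non-negative

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float).ravel()
        self.signal = np.asarray(self.signal, dtype=float)
        if self.echo_times.size < 2:
            raise ValueError("at least two echoes are required")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo_times must be strictly increasing and > 0")
        expected = tuple(self.geometry.shape) + (self.echo_times.size,)
        if self.signal.shape != expected:
            raise ValueError(f"signal shape {self.signal.shape} != {expected}")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size


@dataclass
class R2Map:
    """Per-voxel transverse relaxation rate map with fit diagnostics."""

    geometry: GridGeometry
    r2: np.ndarray  # s^-1
    s0: np.ndarray  # extrapolated zero-echo signal
    fit_quality: np.ndarray  # coefficient of determination in [0, 1]
    valid_mask: np.ndarray  # True where the fit converged

    def __post_init__(self) -> None:
        shp = tuple(self.geometry.shape)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.fit_quality = np.asarray(self.fit_quality, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        for name, arr in (
            ("r2", self.r2),
            ("s0", self.s0),
            ("fit_quality", self.fit_quality),
            ("valid_mask", self.valid_mask),
        ):
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != geometry shape {shp}")
        m = self.valid_mask
        if not np.all(np.isfinite(self.r2[m])):
            raise ValueError("r2 must be finite on the valid mask")
        q = self.fit_quality[m]
        if q.size and (np.any(q < -1e-9) or np.any(q > 1 + 1e-9)):
            raise ValueError("fit_quality must lie in [0, 1] on the valid mask")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii.gz", ".nii")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(".npz"):
        return "npz"
    if name.endswith(".dcm"):
        return "dicom_rtdose"
    raise ValueError(f"cannot infer grid format from file name {path.name!r}")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _NIFTI_SUFFIXES:
        if name.lower().endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_name(path.stem + ".json")


def _affine_from_geometry(geometry: GridGeometry) -> np.ndarray:
    affine = np.diag(list(geometry.spacing) + [1.0])
    affine[:3, 3] = geometry.origin
    return affine


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...], source: str) -> GridGeometry:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(f"{source}: oblique/rotated grids are not supported")
    spacing = np.diag(rot)
    if np.any(spacing == 0):
        raise ValueError(f"{source}: missing or zero voxel spacing in header")
    if np.any(spacing < 0):
        raise ValueError(f"{source}: negative-spacing (flipped) axes are not supported")
    return GridGeometry(shape=tuple(shape), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def write_grid(grid: DoseGrid, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`DoseGrid` to NIfTI (+ JSON sidecar) or ``.npz``.

    Values are stored as 32-bit floats; geometry is stored exactly.
    DICOM RT-Dose is import-only and not a supported output format.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if fmt == "nifti":
        img = nib.Nifti1Image(grid.values.astype(np.float32), _affine_from_geometry(grid.geometry))
        nib.save(img, str(path))
        # NIfTI headers hold the affine as float32; the sidecar keeps the
        # exact geometry alongside the normalization flags
        meta = {
            "normalized": bool(grid.normalized),
            "normalization_value": grid.normalization_value,
            "spacing_mm": list(grid.geometry.spacing),
            "origin_mm": list(grid.geometry.origin),
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    elif fmt == "npz":
        np.savez(
            path,
            values=grid.values.astype(np.float32),
            spacing=np.asarray(grid.geometry.spacing, dtype=float),
            origin=np.asarray(grid.geometry.origin, dtype=float),
            normalized=np.asarray(grid.normalized),
            normalization_value=np.asarray(
                np.nan if grid.normalization_value is None else grid.normalization_value
            ),
        )
    elif fmt == "dicom_rtdose":
        raise ValueError("dicom_rtdose is a read-only format")
    else:
        raise ValueError(f"unsupported grid format {fmt!r}")


def read_grid(path: str | Path, format: str | None = None) -> DoseGrid:
    """Read a dose grid from NIfTI, ``.npz`` or DICOM RT-Dose.

    The file must carry voxel-spacing metadata; values are returned unchanged
    apart from the format's own stored scale factor (``DoseGridScaling`` for
    RT-Dose).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
        geometry = _geometry_from_affine(img.affine, data.shape, str(path))
        normalized, norm_value = False, None
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            normalized = bool(meta.get("normalized", False))
            norm_value = meta.get("normalization_value")
            if "spacing_mm" in meta:  # exact geometry beats the float32 header
                geometry = GridGeometry(
                    data.shape, tuple(meta["spacing_mm"]), tuple(meta.get("origin_mm", geometry.origin))
                )
        return DoseGrid(geometry, data, normalized=normalized, normalization_value=norm_value)
    if fmt == "npz":
        with np.load(path) as f:
            if "spacing" not in f:
                raise ValueError(f"{path}: missing 'spacing' metadata")
            values = np.asarray(f["values"], dtype=float)
            if values.ndim != 3:
                raise ValueError(f"{path}: expected a 3D volume, got {values.ndim}D")
            geometry = GridGeometry(values.shape, tuple(f["spacing"]), tuple(f["origin"]))
            nv = float(f["normalization_value"])
            return DoseGrid(
                geometry,
                values,
                normalized=bool(f["normalized"]),
                normalization_value=None if np.isnan(nv) else nv,
            )
    if fmt == "dicom_rtdose":
        return _read_dicom_rtdose(path)
    raise ValueError(f"unsupported grid format {fmt!r}")


def _read_dicom_rtdose(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    for attr in ("PixelSpacing", "ImagePositionPatient", "GridFrameOffsetVector"):
        if attr not in ds:
            raise ValueError(f"{path}: missing required RT-Dose field {attr}")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    # pixel_array is (frames, rows, cols) == (z, y, x)
    values = ds.pixel_array.astype(float) * scaling
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a multi-frame (3D) dose payload")
    values = np.ascontiguousarray(values.transpose(2, 1, 0))
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size < 2 or not np.allclose(dz, dz[0]):
        raise ValueError(f"{path}: non-uniform GridFrameOffsetVector is not supported")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # row = y pitch, col = x pitch
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    geometry = GridGeometry(values.shape, (col_sp, row_sp, float(dz[0])), origin)
    return DoseGrid(geometry, values)


def write_multiecho(image: MultiEchoImage, path: str | Path) -> None:
    """Write a 4D multi-echo image as NIfTI plus an echo-time JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(image.signal.astype(np.float32), _affine_from_geometry(image.geometry))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "echo_times_s": list(image.echo_times),
                "spacing_mm": list(image.geometry.spacing),
                "origin_mm": list(image.geometry.origin),
            },
            indent=1,
        )
    )


def read_multiecho(path: str | Path, echo_times: Sequence[float] | None = None) -> MultiEchoImage:
    """Read a 4D NIfTI multi-echo image; echo times from the sidecar unless given."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D multi-echo volume, got {data.ndim}D")
    geometry = _geometry_from_affine(img.affine, data.shape[:3], str(path))
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if echo_times is None:
            echo_times = meta["echo_times_s"]
        if "spacing_mm" in meta:
            geometry = GridGeometry(
                data.shape[:3], tuple(meta["spacing_mm"]), tuple(meta.get("origin_mm", geometry.origin))
            )
    if echo_times is None:
        raise ValueError(f"{path}: no echo times given and no sidecar {sidecar.name}")
    return MultiEchoImage(geometry, np.asarray(echo_times, dtype=float), data)


def save_r2_map(r2map: R2Map, path: str | Path) -> None:
    """Persist an :class:`R2Map` as a self-contained ``.npz``.

    Invalid voxels are stored with r2 = 0 and valid_mask false (no NaN in
    files; NaN is kept in memory only).
    """
    r2 = np.where(r2map.valid_mask, r2map.r2, 0.0)
    s0 = np.where(r2map.valid_mask, r2map.s0, 0.0)
    q = np.where(r2map.valid_mask, r2map.fit_quality, 0.0)
    np.savez(
        Path(path),
        r2=r2,
        s0=s0,
        fit_quality=q,
        valid_mask=r2map.valid_mask,
        spacing=np.asarray(r2map.geometry.spacing, dtype=float),
        origin=np.asarray(r2map.geometry.origin, dtype=float),
    )


def load_r2_map(path: str | Path) -> R2Map:
    with np.load(Path(path)) as f:
        geometry = GridGeometry(f["r2"].shape, tuple(f["spacing"]), tuple(f["origin"]))
        return R2Map(geometry, f["r2"], f["s0"], f["fit_quality"], f["valid_mask"])
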