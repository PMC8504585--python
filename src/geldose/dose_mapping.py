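"""Bring the measured (gel/MRI) dose grid into the planned (TPS) frame.

Registration is rigid-only — the gel vial is rigid inside the phantom — and is
estimated from labelled fiducial marks (shaped rods visible in both frames) by
the closed-form least-squares solution: centroid alignment plus the rotation
from the SVD of the cross-covariance, with reflection correction. Resampling
is trilinear; both distributions are then normalized to their isocenter dose
so they can be compared on the same dimensionless scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .grid_model import DoseGrid, GridGeometry, world_to_index

__all__ = [
    "FiducialSet",
    "RigidTransform",
    "rigid_from_fiducials",
    "resample_grid",
    "normalize_to_isocenter",
    "read_fiducials_csv",
    "save_transform",
    "load_transform",
]


@dataclass(frozen=True)
class FiducialSet:
    """Label-aligned fiducial correspondences between two frames (mm)."""

    labels: tuple[str, ...]
    points_measured: np.ndarray  # (n, 3)
    points_planned: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        pm = np.atleast_2d(np.asarray(self.points_measured, dtype=float))
        pp = np.atleast_2d(np.asarray(self.points_planned, dtype=float))
        labels = tuple(str(l) for l in self.labels)
        if pm.shape != pp.shape or pm.shape[1] != 3:
            raise ValueError("measured and planned points must both be (n, 3)")
        if len(labels) != pm.shape[0]:
            raise ValueError("label mismatch: one label per correspondence required")
        if pm.shape[0] < 3:
            raise ValueError("at least 3 fiducial correspondences are required")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points_measured", pm)
        object.__setattr__(self, "points_planned", pp)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``p -> R p + t`` (rotation orthonormal, det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).ravel()
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix must have det = +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rigid_from_fiducials(fiducials: FiducialSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform measured -> planned, and its FRE.

    Kabsch solution: align centroids, take the rotation from the SVD of the
    cross-covariance (reflection corrected). The fiducial registration error
    (FRE) is the RMS residual over the fiducials, in mm.
    """
    m = fiducials.points_measured
    p = fiducials.points_planned
    mc = m - m.mean(axis=0)
    pc = p - p.mean(axis=0)
    # collinear point sets leave the rotation about the common line unconstrained
    if np.linalg.matrix_rank(mc, tol=1e-9 * max(1.0, np.abs(mc).max())) < 2:
        raise ValueError("fiducials are collinear; the rotation is not determined")
    H = mc.T @ pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = p.mean(axis=0) - R @ m.mean(axis=0)
    transform = RigidTransform(R, t)
    resid = transform.apply(m) - p
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, fre


def resample_grid(
    source: DoseGrid,
    transform: RigidTransform,
    target_geometry: GridGeometry,
) -> tuple[DoseGrid, np.ndarray]:
    """Resample ``source`` onto ``target_geometry`` through a rigid transform.

    ``transform`` maps source-frame points into the target frame. Each target
    voxel center is pulled back into the source frame and trilinearly
    interpolated. Returns the resampled grid plus a validity mask; voxels
    falling outside the source grid are 0 and masked False (downstream gamma
    excludes them rather than treating them as zero dose).
    """
    X, Y, Z = target_geometry.voxel_centers()
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    src_pts = transform.inverse().apply(pts)
    idx = (src_pts - np.asarray(source.geometry.origin)) / np.asarray(source.geometry.spacing)
    shape = np.asarray(source.geometry.shape)
    inside = np.all((idx >= 0.0) & (idx <= shape - 1), axis=1)
    values = map_coordinates(source.values, idx.T, order=1, mode="constant", cval=0.0)
    values[~inside] = 0.0
    values = values.reshape(target_geometry.shape)
    mask = inside.reshape(target_geometry.shape)
    return (
        DoseGrid(
            target_geometry,
            values,
            normalized=source.normalized,
            normalization_value=source.normalization_value,
        ),
        mask,
    )


def normalize_to_isocenter(
    grid: DoseGrid,
    isocenter: Sequence[float],
    averaging_radius: float = 3.0,
) -> DoseGrid:
    """Divide a dose grid by its isocenter dose.

    The normalization value is the mean dose over voxels whose centers lie
    within ``averaging_radius`` mm of the isocenter (a small neighborhood
    stabilizes single-voxel noise; radius 0 uses the nearest voxel alone).
    """
    geom = grid.geometry
    iso = np.asarray(isocenter, dtype=float)
    if not geom.contains_index(world_to_index(geom, iso)):
        raise ValueError("isocenter lies outside the grid")
    if averaging_radius < 0:
        raise ValueError("averaging_radius must be >= 0")
    X, Y, Z = geom.voxel_centers()
    sphere = (X - iso[0]) ** 2 + (Y - iso[1]) ** 2 + (Z - iso[2]) ** 2 <= averaging_radius**2
    if not sphere.any():
        sphere = np.zeros(geom.shape, dtype=bool)
        sphere[geom.nearest_voxel(iso)] = True
    norm = float(grid.values[sphere].mean())
    if norm <= 0:
        raise ValueError("non-positive dose at the isocenter; cannot normalize")
    # keep the Gy meaning of the original normalization when re-normalizing
    norm_gy = norm if not grid.normalized else (grid.normalization_value or norm)
    return DoseGrid(geom, grid.values / norm, normalized=True, normalization_value=norm_gy)


# ---------------------------------------------------------------------------
# Plumbing: fiducial CSV and transform JSON
# ---------------------------------------------------------------------------


def read_fiducials_csv(path: str | Path) -> FiducialSet:
    """Read fiducials from CSV with columns label, frame, x, y, z.

    ``frame`` is 'measured' or 'planned'; rows are matched by label.
    """
    df = pd.read_csv(path)
    required = {"label", "frame", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"fiducial CSV needs columns {sorted(required)}")
    measured = df[df["frame"] == "measured"].set_index("label")
    planned = df[df["frame"] == "planned"].set_index("label")
    labels = sorted(set(measured.index) & set(planned.index))
    if len(labels) < len(measured) or len(labels) < len(planned):
        raise ValueError("label mismatch between measured and planned fiducials")
    return FiducialSet(
        tuple(labels),
        measured.loc[labels, ["x", "y", "z"]].to_numpy(float),
        planned.loc[labels, ["x", "y", "z"]].to_numpy(float),
    )


def save_transform(transform: RigidTransform, path: str | Path, fre: float | None = None) -> None:
    payload = {
        "rotation": transform.rotation.tolist(),
        "translation": transform.translation.tolist(),
    }
    if fre is not None:
        payload["fre_mm"] = fre
    Path(path).write_text(json.dumps(payload, indent=1))


def load_transform(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))
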