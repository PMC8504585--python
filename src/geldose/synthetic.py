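"""Synthetic study generator: box-technique planned dose, multi-echo MRI of the
gel insert, calibration-tube tables and TLD readings.

This module stands in for the physical experiment — pelvic phantom, linac,
treatment planning system and MR scanner — with the statistical structure the
analysis assumes:

* a four-field box plan (gantry 0/90/180/270) delivering a prescribed dose at
  the isocenter, computed with a pedagogical broad-beam model (linear build-up
  to d_max, exponential attenuation beyond it, error-function penumbra). It is
  emphatically **not** a TPS emulator;
* an optional phenomenological metal-prosthesis perturbation: exponential
  beam attenuation through a cylinder (``transmission`` per diameter
  traversed) plus a proximal interface enhancement on the beam-entry side —
  magnitudes are user parameters, not physics claims;
* a mono-exponential multi-spin-echo signal ``S(TE) = S0 exp(-TE * R2)`` with
  R2 tied to dose through a linear calibration curve, and optional Gaussian or
  Rician magnitude noise;
* linear calibration-tube and TLD responses with Gaussian scatter.

All randomness flows from one explicit integer seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .calibration import CalibrationCurve
from .grid_model import DoseGrid, GridGeometry, MultiEchoImage, world_to_index

__all__ = [
    "BeamConfig",
    "Prosthesis",
    "PhantomModel",
    "NoiseModel",
    "default_beams",
    "default_phantom",
    "simulate_box_dose",
    "simulate_multiecho_mri",
    "simulate_calibration_tubes",
    "simulate_tld_readings",
    "DEFAULT_ECHO_TIMES_S",
]

# 8-echo acquisition, echo spacing 35 ms (protocol emulated by default)
DEFAULT_ECHO_TIMES_S: np.ndarray = 0.035 * np.arange(1, 9)


@dataclass(frozen=True)
class BeamConfig:
    """One broad beam of the box technique.

    ``gantry_angle`` follows the IEC convention projected on the axial plane:
    0 enters anteriorly (travels -y), 90 from the patient's left (travels -x),
    180 posteriorly (+y), 270 from the right (+x). ``field_size`` is the
    (cross-plane, cranio-caudal) aperture in cm at the isocenter.
    ``mu_water`` is the effective broad-beam attenuation coefficient (mm^-1),
    ``dmax_depth`` the build-up depth (mm) and ``penumbra_sigma`` the Gaussian
    edge blur of the field aperture (mm); defaults are 6-MV-scale values.
    """

    gantry_angle: float
    field_size: tuple[float, float] = (8.8, 11.5)
    weight: float = 1.0
    mu_water: float = 0.005
    penumbra_sigma: float = 3.0
    dmax_depth: float = 15.0

    def __post_init__(self) -> None:
        if self.gantry_angle % 90 != 0:
            raise ValueError("box-technique beams must sit at gantry 0/90/180/270")
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if self.mu_water <= 0:
            raise ValueError("mu_water must be > 0")
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        if self.dmax_depth <= 0:
            raise ValueError("dmax_depth must be > 0")

    @property
    def direction(self) -> np.ndarray:
        g = np.deg2rad(self.gantry_angle % 360)
        d = np.array([-np.sin(g), -np.cos(g), 0.0])
        d[np.abs(d) < 1e-12] = 0.0
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class Prosthesis:
    """Cylindrical high-Z implant perturbing the beams phenomenologically.

    ``transmission`` is the fraction of primary fluence left after traversing
    one full diameter; ``interface_boost`` adds scatter enhancement within
    ``boost_range`` mm of the surface on the beam-entry side.
    """

    center: tuple[float, float, float]
    radius: float
    length: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    transmission: float = 0.8
    interface_boost: float = 0.0
    boost_range: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must lie in (0, 1]")
        if self.interface_boost < 0:
            raise ValueError("interface_boost must be >= 0")
        if self.radius <= 0 or self.length <= 0 or self.boost_range <= 0:
            raise ValueError("radius, length and boost_range must be > 0")
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("degenerate prosthesis axis")

    @property
    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        return a / np.linalg.norm(a)


@dataclass(frozen=True)
class PhantomModel:
    """Geometry of the irradiated phantom: grid, body box, isocenter, implants."""

    geometry: GridGeometry
    body_extent: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    isocenter: tuple[float, float, float]
    prostheses: tuple[Prosthesis, ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in self.body_extent:
            if not lo < hi:
                raise ValueError("body_extent intervals must be ordered (lo < hi)")
        iso = self.isocenter
        if not all(
            self.body_extent[k][0] <= iso[k] <= self.body_extent[k][1] for k in range(3)
        ):
            raise ValueError("isocenter must lie inside body_extent")


@dataclass(frozen=True)
class NoiseModel:
    """MRI magnitude-noise description (phenomenological, incl. edge effects)."""

    kind: str = "none"  # none | gaussian | rician
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_beams(weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0), **kwargs) -> list[BeamConfig]:
    """Four equal-weight (by default) box beams at gantry 0/90/180/270."""
    if len(weights) != 4:
        raise ValueError("exactly four beam weights expected")
    return [
        BeamConfig(gantry_angle=g, weight=w, **kwargs)
        for g, w in zip((0.0, 90.0, 180.0, 270.0), weights)
    ]


def default_phantom(
    shape: tuple[int, int, int] = (64, 64, 32),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    prostheses: Sequence[Prosthesis] = (),
) -> PhantomModel:
    """Desk-scale phantom (default 64x64x32 @ 3 mm), isocenter at the grid
    center, body filling the grid. The study-scale acquisition grid is
    ``shape=(224, 224, 60), spacing=(0.6, 0.6, 2.0)``.
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    geometry = GridGeometry(shape, spacing, origin)
    extent = tuple(
        (origin[k] - spacing[k] / 2, origin[k] + (shape[k] - 0.5) * spacing[k])
        for k in range(3)
    )
    return PhantomModel(geometry, extent, (0.0, 0.0, 0.0), tuple(prostheses))


# ---------------------------------------------------------------------------
# Planned-dose simulation
# ---------------------------------------------------------------------------


def _edge_profile(u: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Error-function-smoothed top-hat, 1 inside |u| < half_width."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((half_width - u) / s) + erf((half_width + u) / s))


def _prosthesis_factors(
    pros: Prosthesis,
    points: tuple[np.ndarray, np.ndarray, np.ndarray],
    direction: np.ndarray,
    depth: np.ndarray,
) -> np.ndarray:
    """Multiplicative perturbation of one beam by one cylinder.

    Attenuation: transmission^(chord / (2*radius)) where chord is the length of
    the upstream ray segment (from the body-entry plane to the voxel) inside
    the cylinder. Enhancement: voxels outside the metal, within boost_range of
    its surface and on the beam-entry side, gain 1 + boost*exp(-s/boost_range).
    """
    a = pros.unit_axis
    c = np.asarray(pros.center, dtype=float)
    mx, my, mz = (points[k] - c[k] for k in range(3))
    m_dot_a = mx * a[0] + my * a[1] + mz * a[2]
    d_dot_a = float(direction @ a)
    # components perpendicular to the cylinder axis
    bx, by, bz = mx - m_dot_a * a[0], my - m_dot_a * a[1], mz - m_dot_a * a[2]
    ax_, ay_, az_ = direction - d_dot_a * a
    A = ax_**2 + ay_**2 + az_**2  # scalar
    B = bx * ax_ + by * ay_ + bz * az_
    C = bx**2 + by**2 + bz**2 - pros.radius**2

    big = 1e30
    if A < 1e-15:
        # beam parallel to the cylinder axis: radially inside => all t intersect
        t_lo_r = np.where(C < 0, -big, big)
        t_hi_r = np.where(C < 0, big, -big)
    else:
        disc = B**2 - A * C
        hit = disc > 0
        sq = np.sqrt(np.clip(disc, 0, None))
        t_lo_r = np.where(hit, (B - sq) / A, big)
        t_hi_r = np.where(hit, (B + sq) / A, -big)

    # axial clip: |m_dot_a - t*d_dot_a| <= length/2 along the upstream ray q(t) = p - t*d
    half_len = pros.length / 2.0
    if abs(d_dot_a) < 1e-15:
        inside_ax = np.abs(m_dot_a) <= half_len
        t_lo_a = np.where(inside_ax, -big, big)
        t_hi_a = np.where(inside_ax, big, -big)
    else:
        t1 = (m_dot_a - half_len) / d_dot_a
        t2 = (m_dot_a + half_len) / d_dot_a
        t_lo_a, t_hi_a = np.minimum(t1, t2), np.maximum(t1, t2)

    t_lo = np.maximum(np.maximum(t_lo_r, t_lo_a), 0.0)
    t_hi = np.minimum(np.minimum(t_hi_r, t_hi_a), depth)
    chord = np.clip(t_hi - t_lo, 0.0, None)
    factor = pros.transmission ** (chord / (2.0 * pros.radius))

    if pros.interface_boost > 0:
        rho = np.sqrt(bx**2 + by**2 + bz**2)
        radial_gap = np.clip(rho - pros.radius, 0.0, None)
        axial_gap = np.clip(np.abs(m_dot_a) - half_len, 0.0, None)
        outside = (rho >= pros.radius) | (np.abs(m_dot_a) > half_len)
        s = np.sqrt(radial_gap**2 + axial_gap**2)
        upstream = (mx * direction[0] + my * direction[1] + mz * direction[2]) < 0
        sel = outside & upstream & (s <= pros.boost_range)
        factor = factor * np.where(
            sel, 1.0 + pros.interface_boost * np.exp(-s / pros.boost_range), 1.0
        )
    return factor


def simulate_box_dose(
    phantom: PhantomModel,
    beams: Sequence[BeamConfig],
    prescription: float = 2.0,
    include_prostheses: bool = True,
) -> DoseGrid:
    """Broad-beam dose of a box plan, rescaled to the prescription at the isocenter.

    Each beam contributes ``weight * PDD(depth) * profile_u * profile_v``,
    where depth is measured from the body surface along the (axis-aligned)
    beam direction, PDD ramps linearly from the surface to ``dmax_depth`` and
    decays ``exp(-mu_water*(d - dmax))`` beyond it, and the lateral profile is
    the product of two erf-smoothed top-hat edges. Prosthesis perturbations
    multiply in when ``include_prostheses`` is set. The summed grid is then
    rescaled so the nearest voxel to the isocenter carries exactly
    ``prescription`` Gy (the box plan's beam-weight tuning, collapsed to one
    scalar).
    """
    if not beams:
        raise ValueError("at least one beam is required")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    weights = np.array([b.weight for b in beams], dtype=float)
    if np.all(weights == 0):
        raise ValueError("all beam weights are zero")
    geom = phantom.geometry
    iso = np.asarray(phantom.isocenter, dtype=float)
    iso_idx = np.rint(world_to_index(geom, iso)).astype(int)
    if not geom.contains_index(iso_idx):
        raise ValueError("isocenter lies outside the dose grid")

    X, Y, Z = geom.voxel_centers()
    coords = (X, Y, Z)
    body = np.ones(geom.shape, dtype=bool)
    for k in range(3):
        lo, hi = phantom.body_extent[k]
        body &= (coords[k] >= lo) & (coords[k] <= hi)

    total = np.zeros(geom.shape, dtype=float)
    for beam in beams:
        if beam.weight == 0:
            continue
        d = beam.direction
        axis = int(np.argmax(np.abs(d)))
        sgn = np.sign(d[axis])
        lo, hi = phantom.body_extent[axis]
        depth = (coords[axis] - lo) if sgn > 0 else (hi - coords[axis])
        pdd = np.where(
            depth < beam.dmax_depth,
            np.clip(depth, 0.0, None) / beam.dmax_depth,
            np.exp(-beam.mu_water * (depth - beam.dmax_depth)),
        )
        # lateral axes: the in-plane transverse axis takes field x, z takes field y
        trans_axis = 1 - axis  # 0 <-> 1 within the axial plane
        u = coords[trans_axis] - iso[trans_axis]
        v = coords[2] - iso[2]
        fx, fy = 10.0 * beam.field_size[0], 10.0 * beam.field_size[1]
        dose_b = (
            beam.weight
            * pdd
            * _edge_profile(u, fx / 2.0, beam.penumbra_sigma)
            * _edge_profile(v, fy / 2.0, beam.penumbra_sigma)
        )
        if include_prostheses:
            for pros in phantom.prostheses:
                dose_b = dose_b * _prosthesis_factors(pros, coords, d, depth)
        total += dose_b
    total *= body

    iso_dose = total[tuple(iso_idx)]
    if iso_dose <= 0:
        raise ValueError("zero dose at the isocenter; check beam/phantom configuration")
    total *= prescription / iso_dose
    return DoseGrid(geom, total)


# ---------------------------------------------------------------------------
# Measurement simulators
# ---------------------------------------------------------------------------


def simulate_multiecho_mri(
    dose: DoseGrid,
    curve: CalibrationCurve,
    echo_times: Sequence[float] = DEFAULT_ECHO_TIMES_S,
    s0: float = 1000.0,
    noise: NoiseModel = NoiseModel(),
) -> MultiEchoImage:
    """Multi-spin-echo magnitude image of an irradiated gel volume.

    Per voxel, ``R2 = curve(dose)`` and ``S(TE_k) = s0 * exp(-TE_k * R2)``.
    Rician noise takes the magnitude of a complex Gaussian perturbation
    (the physically right model for magnitude MRI); Gaussian noise is additive
    with negatives clipped at zero. Deterministic given ``noise.seed``.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if dose.normalized:
        raise ValueError("dose must be in Gy (not normalized) to synthesize MRI signal")
    te = np.asarray(echo_times, dtype=float).ravel()
    r2_true = curve.intercept + curve.slope * dose.values
    signal = s0 * np.exp(-te[None, None, None, :] * r2_true[..., None])
    if noise.kind != "none" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        if noise.kind == "gaussian":
            signal = np.clip(signal + rng.normal(0.0, noise.sigma, signal.shape), 0.0, None)
        else:  # rician
            n_re = rng.normal(0.0, noise.sigma, signal.shape)
            n_im = rng.normal(0.0, noise.sigma, signal.shape)
            signal = np.hypot(signal + n_re, n_im)
    return MultiEchoImage(dose.geometry, te, signal)


def simulate_calibration_tubes(
    doses: Sequence[float],
    curve: CalibrationCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """ROI summaries of the calibration tubes: (dose, mean R2, sd R2) per tube.

    Mean R2 sits on the calibration line plus Gaussian(0, noise_sd) scatter;
    the sd column carries ``noise_sd`` (the between-slice ROI spread the error
    bars of a measured calibration curve represent). Deterministic given seed.
    """
    d = np.asarray(doses, dtype=float).ravel()
    if np.any(d < 0):
        raise ValueError("tube doses must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mean_r2 = curve.intercept + curve.slope * d
    if noise_sd > 0:
        mean_r2 = mean_r2 + rng.normal(0.0, noise_sd, d.shape)
    return pd.DataFrame(
        {"dose_gy": d, "mean_r2": mean_r2, "sd_r2": np.full_like(d, float(noise_sd))}
    )


def simulate_tld_readings(
    true_doses: Sequence[float],
    sensitivity: float,
    relative_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Linear-response TLD readings: ``sensitivity * dose * (1 + N(0, relative_sd))``."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if relative_sd < 0:
        raise ValueError("relative_sd must be >= 0")
    d = np.asarray(true_doses, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    factor = 1.0 + (rng.normal(0.0, relative_sd, d.shape) if relative_sd > 0 else 0.0)
    return sensitivity * d * factor
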