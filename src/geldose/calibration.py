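"""Linear dose calibration of the gel (R2 vs dose) and of the TLD chips.

Polymer-gel dosimeters respond to absorbed dose with a linear increase of the
water-proton transverse relaxation rate, R2 = a + b*D, over their working
range; fitting that line to calibration-tube measurements and inverting it
converts an R2 map into a 3D dose map. TLD chips are modelled with a
through-origin linear response (zero reading at zero dose).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .grid_model import DoseGrid, R2Map

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "r2_to_dose",
    "calibrate_tld",
    "reading_to_dose",
    "save_curve",
    "load_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear R2--dose relation: ``R2 = intercept + slope * D``.

    Units: intercept (and its SE) in s^-1, slope (and its SE) in s^-1 Gy^-1.
    ``dose_range`` records the Gy span the curve was calibrated over;
    extrapolation outside it is allowed but logged (gel response saturates
    outside the calibrated range).
    """

    intercept: float
    slope: float
    intercept_se: float = float("nan")
    slope_se: float = float("nan")
    pearson_r: float = float("nan")
    dose_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dose_range[0] > self.dose_range[1]:
            raise ValueError("dose_range must be ordered (low, high)")
        if np.isfinite(self.pearson_r) and not -1 - 1e-12 <= self.pearson_r <= 1 + 1e-12:
            raise ValueError("pearson_r must lie in [-1, 1]")

    def r2_at(self, dose: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(dose, dtype=float)


def fit_calibration(
    doses: np.ndarray,
    r2_means: np.ndarray,
    r2_sds: np.ndarray | None = None,
) -> CalibrationCurve:
    """Fit the linear gel calibration ``R2 = a + b*D`` to tube measurements.

    Weighted least squares with weights 1/sd^2 when per-tube standard
    deviations are supplied (unweighted otherwise). Standard errors come from
    the covariance of the linear fit: for a weighted fit the sds are taken as
    known measurement errors, so cov = (X^T W X)^-1; for an unweighted fit the
    residual variance (n-2 df) scales (X^T X)^-1.

    ``pearson_r`` is the plain correlation of (dose, mean R2).
    """
    d = np.asarray(doses, dtype=float).ravel()
    y = np.asarray(r2_means, dtype=float).ravel()
    if d.size != y.size:
        raise ValueError("doses and r2_means must have the same length")
    if d.size < 2:
        raise ValueError("at least two calibration points are required")
    if np.ptp(d) == 0:
        raise ValueError("doses must not all be equal")
    if r2_sds is not None:
        sd = np.asarray(r2_sds, dtype=float).ravel()
        if sd.size != d.size:
            raise ValueError("r2_sds must match doses in length")
        if np.any(sd <= 0):
            raise ValueError("r2_sds must be strictly positive")
        w = 1.0 / sd**2
    else:
        w = np.ones_like(d)

    X = np.column_stack([np.ones_like(d), d])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    cov_unscaled = np.linalg.inv(xtwx)
    if r2_sds is not None:
        cov = cov_unscaled
    elif d.size > 2:
        cov = cov_unscaled * float(resid @ resid) / (d.size - 2)
    else:
        cov = np.full((2, 2), np.nan)

    if np.ptp(y) == 0:
        r = 0.0 if np.ptp(d) else float("nan")
    else:
        r = float(stats.pearsonr(d, y).statistic)
    return CalibrationCurve(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_se=float(np.sqrt(cov[0, 0])),
        slope_se=float(np.sqrt(cov[1, 1])),
        pearson_r=r,
        dose_range=(float(d.min()), float(d.max())),
    )


def r2_to_dose(r2map: R2Map, curve: CalibrationCurve, clamp_negative: bool = True) -> DoseGrid:
    """Invert the calibration line: ``D = (R2 - intercept) / slope`` per voxel.

    Invalid voxels map to 0 Gy (the validity mask travels with the R2 map).
    Negative doses (R2 below the intercept, i.e. noise) are clamped to 0 by
    default. Doses outside the calibrated range are allowed but logged.
    """
    if not np.isfinite(curve.slope) or curve.slope <= 0:
        raise ValueError("calibration slope must be > 0 to invert R2 to dose")
    dose = (np.where(r2map.valid_mask, r2map.r2, curve.intercept) - curve.intercept) / curve.slope
    if clamp_negative:
        dose = np.clip(dose, 0.0, None)
    elif np.any(dose < 0):
        # Physical doses are non-negative; refuse to emit a grid violating that.
        raise ValueError(
            "inversion produced negative doses; pass clamp_negative=True to clip them"
        )
    lo, hi = curve.dose_range
    if hi > lo:
        n_out = int(np.sum((dose > hi) & r2map.valid_mask))
        if n_out:
            log.warning(
                "%d voxels above the calibrated dose range (%.3g-%.3g Gy); "
                "gel response may saturate there",
                n_out,
                lo,
                hi,
            )
    return DoseGrid(r2map.geometry, dose)


def calibrate_tld(readings: np.ndarray, doses: np.ndarray) -> tuple[float, float]:
    """Through-origin linear TLD calibration.

    Returns ``(sensitivity, pearson_r)`` with
    ``sensitivity = sum(reading*dose) / sum(dose^2)`` (reader units per Gy) and
    the plain correlation of (dose, reading). A single calibration point gives
    ``pearson_r = nan``.
    """
    r = np.asarray(readings, dtype=float).ravel()
    d = np.asarray(doses, dtype=float).ravel()
    if r.size != d.size or r.size < 1:
        raise ValueError("readings and doses must be equal-length, non-empty vectors")
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("doses must not all be zero")
    sensitivity = float(r @ d) / denom
    if d.size < 2 or np.ptp(d) == 0 or np.ptp(r) == 0:
        pear = float("nan")
    else:
        pear = float(stats.pearsonr(d, r).statistic)
    return sensitivity, pear


def reading_to_dose(reading: float, sensitivity: float, chip_factor: float = 1.0) -> float:
    """Convert a TLD reading to dose: ``D = reading / (sensitivity * chip_factor)``."""
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if chip_factor <= 0:
        raise ValueError("chip_factor must be > 0")
    return float(reading) / (sensitivity * chip_factor)


def save_curve(curve: CalibrationCurve, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(curve), indent=1))


def load_curve(path: str | Path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    d["dose_range"] = tuple(d["dose_range"])
    return CalibrationCurve(**d)
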