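"""TLD point-dose comparison: per-dosimeter deviations and regional summaries.

Seven LiF chips per side of the pelvis (four around the femur, two at the
acetabulum, one at the sacrum) measure point doses that are compared to the
TPS planned dose at the same positions as percent deviations
``100 * (measured - planned) / planned``. Regional means average the
per-dosimeter percent deviations (not deviations of mean doses). Compromised
chips are first-class absent values, excluded from every mean and count.

When a report is rebuilt from a published table of one-decimal doses, the
printed deviations may not be reproducible from the printed doses (they were
computed from unrounded values); such rows are preserved verbatim and flagged
inconsistent rather than "corrected".
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_model import DoseGrid

__all__ = [
    "TldRecord",
    "TldReport",
    "percent_deviation",
    "build_report",
    "mean_tps_dose_in_volume",
    "check_table_consistency",
    "bilateral_prosthesis_example_records",
    "read_records_csv",
    "write_records_csv",
]

log = logging.getLogger(__name__)

SIDES = ("left", "right")
REGIONS = ("femur", "acetabulum", "sacrum")


@dataclass(frozen=True)
class TldRecord:
    """One dosimeter: position labels, measured and planned dose (Gy).

    ``measured_dose`` is None for a compromised chip. ``deviation_percent``
    may carry a published (tabulated) deviation; when absent it is derived
    from the doses at full precision.
    """

    dosimeter_id: int
    side: str
    region: str
    measured_dose: float | None
    planned_dose: float
    deviation_percent: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.dosimeter_id) <= 7:
            raise ValueError("dosimeter_id must be 1-7")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if self.planned_dose <= 0:
            raise ValueError("planned_dose must be > 0")
        if self.measured_dose is None and self.deviation_percent is not None:
            raise ValueError("deviation requires a measured dose")

    def deviation(self, tabulated: bool = False) -> float | None:
        """Percent deviation: the tabulated value if requested and present,
        otherwise computed from the doses; None when measured is absent."""
        if self.measured_dose is None:
            return None
        if tabulated and self.deviation_percent is not None:
            return float(self.deviation_percent)
        return percent_deviation(self.measured_dose, self.planned_dose)


@dataclass
class TldReport:
    """Per-record deviations plus regional means per (side, region)."""

    records: list[TldRecord]
    regional_means: dict[tuple[str, str], float]
    regional_mean_doses: dict[tuple[str, str], tuple[float, float]]

    def to_frame(self, tabulated: bool = False) -> pd.DataFrame:
        rows = []
        for r in self.records:
            dev = r.deviation(tabulated=tabulated)
            rows.append(
                {
                    "id": r.dosimeter_id,
                    "side": r.side,
                    "region": r.region,
                    "measured_gy": r.measured_dose,
                    "planned_gy": r.planned_dose,
                    "deviation_percent": None if dev is None else round(dev, 1),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": self.to_frame().to_dict(orient="records"),
                "regional_mean_deviation_percent": {
                    f"{s}/{r}": round(v, 1) for (s, r), v in self.regional_means.items()
                },
                "regional_mean_doses_gy": {
                    f"{s}/{r}": [round(m, 2), round(p, 2)]
                    for (s, r), (m, p) in self.regional_mean_doses.items()
                },
            },
            indent=1,
        )

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown(index=False)


def percent_deviation(measured: float | None, planned: float) -> float | None:
    """``100 * (measured - planned) / planned``; None for an absent measurement.

    Full precision is retained; tables round to one decimal at output time.
    """
    if planned <= 0:
        raise ValueError("planned dose must be > 0")
    if measured is None:
        return None
    return 100.0 * (measured - planned) / planned


def build_report(records: list[TldRecord], tabulated: bool = False) -> TldReport:
    """Regional summary of a set of TLD records.

    Regional mean deviation = arithmetic mean of the present per-record
    percent deviations in each (side, region) group. ``tabulated=True`` means
    "as printed": records carrying a published deviation contribute that value
    instead of one recomputed from the (rounded) doses — the mode to use when
    rebuilding a published table. Regional mean doses are (mean measured,
    mean planned) over records with a present measurement. Groups with no
    present measurement get no entry (logged).
    """
    means: dict[tuple[str, str], float] = {}
    mean_doses: dict[tuple[str, str], tuple[float, float]] = {}
    for side in SIDES:
        for region in REGIONS:
            group = [r for r in records if r.side == side and r.region == region]
            if not group:
                continue
            devs = [d for d in (r.deviation(tabulated=tabulated) for r in group) if d is not None]
            present = [r for r in group if r.measured_dose is not None]
            if not devs:
                log.warning("no usable measurements for %s/%s; group skipped", side, region)
                continue
            means[(side, region)] = float(np.mean(devs))
            mean_doses[(side, region)] = (
                float(np.mean([r.measured_dose for r in present])),
                float(np.mean([r.planned_dose for r in present])),
            )
    return TldReport(list(records), means, mean_doses)


def check_table_consistency(records: list[TldRecord], tol: float = 0.05) -> dict[tuple[str, int], bool]:
    """Check each record's published deviation against its published doses.

    Returns {(side, id): consistent} for records that carry a tabulated
    deviation; a row is consistent when the deviation recomputed from the
    printed doses matches the printed deviation within ``tol`` percentage
    points (one-decimal rounding slack). Inconsistent rows are legitimate —
    published deviations are often computed from unrounded doses — and are
    reported rather than corrected.
    """
    out: dict[tuple[str, int], bool] = {}
    for r in records:
        if r.deviation_percent is None or r.measured_dose is None:
            continue
        computed = percent_deviation(r.measured_dose, r.planned_dose)
        out[(r.side, r.dosimeter_id)] = bool(abs(computed - r.deviation_percent) <= tol)
    return out


def mean_tps_dose_in_volume(dose: DoseGrid, mask: np.ndarray) -> float:
    """Mean planned dose over the voxels of a delineated chip volume."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(dose.geometry.shape):
        raise ValueError("mask shape must match the dose grid")
    if not mask.any():
        raise ValueError("empty mask")
    return float(dose.values[mask].mean())


def bilateral_prosthesis_example_records() -> list[TldRecord]:
    """Bundled example dataset: 14 TLD around bilateral steel hip prostheses.

    Published point-dose table from a pelvic-phantom box-technique study
    (doses in Gy rounded to one decimal, deviations as printed; right
    dosimeter 1 was compromised by water contact and has no measurement).
    """
    rows = [
        # (id, side, region, measured, planned, printed deviation)
        (1, "left", "femur", 0.5, 0.6, -8.5),
        (2, "left", "femur", 1.4, 1.2, 12.0),
        (3, "left", "femur", 2.3, 2.6, -9.1),
        (4, "left", "femur", 2.2, 2.2, 0.0),
        (5, "left", "acetabulum", 2.3, 2.5, -7.2),
        (6, "left", "acetabulum", 3.9, 3.8, 1.3),
        (7, "left", "sacrum", 3.7, 3.6, 2.8),
        (1, "right", "femur", None, 0.6, None),
        (2, "right", "femur", 0.8, 0.5, 55.6),
        (3, "right", "femur", 1.6, 0.8, 102.9),
        (4, "right", "femur", 1.5, 0.6, 150.0),
        (5, "right", "acetabulum", 2.6, 2.6, -1.2),
        (6, "right", "acetabulum", 2.3, 2.5, -8.5),
        (7, "right", "sacrum", 3.8, 3.8, 1.1),
    ]
    return [TldRecord(*row) for row in rows]


def read_records_csv(path: str | Path) -> list[TldRecord]:
    """Read records from CSV (id, side, region, measured_gy, planned_gy
    [, deviation_percent]); empty measured cells mean a compromised chip."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        measured = row["measured_gy"]
        dev = row.get("deviation_percent", np.nan)
        records.append(
            TldRecord(
                int(row["id"]),
                str(row["side"]),
                str(row["region"]),
                None if pd.isna(measured) else float(measured),
                float(row["planned_gy"]),
                None if pd.isna(dev) else float(dev),
            )
        )
    return records


def write_records_csv(records: list[TldRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.dosimeter_id,
                "side": r.side,
                "region": r.region,
                "measured_gy": r.measured_dose,
                "planned_gy": r.planned_dose,
                "deviation_percent": r.deviation_percent,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
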