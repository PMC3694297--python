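"""Apparent permeability from sequential receiver-well scintillation data.

The insert is moved through a series of fresh receiver wells; each collected
well holds the tracer that crossed during one interval.  The donor-volume
equivalent cleared of tracer in an interval is

    cleared volume (μl) = M_R (dpm) / C_D (dpm/μl)

with M_R the background-corrected receiver amount and C_D the measured donor
concentration.  Cumulative cleared volume is linear in time while the receiver
stays an approximate sink; its slope from ordinary least squares is the PS
product (permeability × surface area) and

    Papp (cm/s) = PS (cm³/s) / A (cm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import InsertGeometry

#: μl/min → cm³/s
UL_PER_MIN_TO_CM3_PER_S = 1e-3 / 60.0


@dataclass(frozen=True)
class ClearanceSeries:
    """Receiver counts for one insert across the transfer schedule."""

    insert_id: str
    times_min: tuple[float, ...]
    receiver_dpm: tuple[float, ...]
    donor_dpm_per_ul: float
    background_dpm: float = 0.0
    geometry: InsertGeometry = field(default_factory=InsertGeometry)

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.receiver_dpm):
            raise ValueError("times and receiver counts differ in length")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("collection times must be strictly increasing")
        if any(d < 0 for d in self.receiver_dpm):
            raise ValueError("receiver dpm must be non-negative")
        if not self.donor_dpm_per_ul > 0:
            raise ValueError("donor concentration must be > 0")


@dataclass(frozen=True)
class PappResult:
    insert_id: str
    slope_ul_per_min: float
    intercept_ul: float
    r_squared: float
    n_points: int
    ps_cm3_per_s: float
    papp_cm_s: float


def clearance_curve(series: ClearanceSeries) -> list[tuple[float, float]]:
    """Cumulative cleared volume (μl) at each collection time.

    Each transfer starts a fresh receiver well, so per-interval cleared
    volumes are summed.  Background-corrected counts that fall below zero are
    clamped to zero with a warning (counting noise near background).
    """
    corrected = np.asarray(series.receiver_dpm, dtype=float) - series.background_dpm
    if (corrected < 0).any():
        warnings.warn(
            f"insert {series.insert_id}: receiver dpm below background clamped to 0",
            stacklevel=2,
        )
        corrected = np.clip(corrected, 0.0, None)
    interval_volumes = corrected / series.donor_dpm_per_ul
    cumulative = np.cumsum(interval_volumes)
    return list(zip(series.times_min, cumulative.tolist()))


def fit_papp(
    clearance: list[tuple[float, float]],
    geom: InsertGeometry,
    insert_id: str = "",
    through_origin: bool = False,
) -> PappResult:
    """Least-squares slope of the clearance curve → PS product → Papp.

    The default regression carries a free intercept, which absorbs dead
    volume and mixing offsets; a through-origin fit is available for
    schedules with very few points.
    """
    if len(clearance) < 2:
        raise ValueError("at least two clearance points are required")
    t = np.asarray([p[0] for p in clearance], dtype=float)
    v = np.asarray([p[1] for p in clearance], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("clearance times have zero variance")

    if through_origin:
        slope = float(t @ v / (t @ t))
        intercept = 0.0
        resid = v - slope * t
        ss_tot = float(((v - v.mean()) ** 2).sum())
        r_squared = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float((resid**2).sum()) / ss_tot)
    else:
        fit = stats.linregress(t, v)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue) ** 2

    ps = slope * UL_PER_MIN_TO_CM3_PER_S
    return PappResult(
        insert_id=insert_id,
        slope_ul_per_min=slope,
        intercept_ul=intercept,
        r_squared=r_squared,
        n_points=len(clearance),
        ps_cm3_per_s=ps,
        papp_cm_s=ps / geom.area_cm2,
    )


def process_clearance_table(
    table: pd.DataFrame,
    geom: InsertGeometry = InsertGeometry(),
    through_origin: bool = False,
) -> pd.DataFrame:
    """Per-insert Papp results from a long-format clearance table.

    Expects columns ``insert_id, time_min, receiver_dpm, donor_dpm_per_ul,
    background_dpm`` (the last two constant within an insert).
    """
    required = {"insert_id", "time_min", "receiver_dpm", "donor_dpm_per_ul", "background_dpm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clearance table is missing columns: {sorted(missing)}")
    rows = []
    for insert_id, grp in table.groupby("insert_id", sort=False):
        grp = grp.sort_values("time_min")
        series = ClearanceSeries(
            insert_id=str(insert_id),
            times_min=tuple(grp["time_min"].astype(float)),
            receiver_dpm=tuple(grp["receiver_dpm"].astype(float)),
            donor_dpm_per_ul=float(grp["donor_dpm_per_ul"].iloc[0]),
            background_dpm=float(grp["background_dpm"].iloc[0]),
            geometry=geom,
        )
        res = fit_papp(clearance_curve(series), geom, insert_id=str(insert_id),
                       through_origin=through_origin)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
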