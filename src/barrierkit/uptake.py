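"""Distribution volumes for dual-label uptake/efflux assays and ALP activity.

Cellular tracer accumulation is expressed as a distribution volume: the volume
of uptake medium holding the same radioactivity as the cells,

    Vd (μl) = dpm in cells / (dpm in medium aliquot / aliquot volume (μl)),

normalised per mg of cell protein.  The substrate channel (e.g. [3H]colchicine,
a P-gp substrate) is corrected for non-specific binding and residual
extracellular fluid by subtracting the Vd of a co-dosed non-permeant marker
([14C]sucrose).  Efflux-pump function is summarised as the "factor increase":
the ratio of mean corrected Vd with inhibitor (verapamil) over control.

Alkaline phosphatase activity is the endpoint pNPP absorbance at 405 nm per
mg protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FactorIncrease:
    factor: float
    mean_test: float
    mean_control: float
    n_test: int
    n_control: int


def distribution_volume(
    cell_dpm: float,
    aliquot_dpm: float,
    aliquot_volume_ul: float,
    protein_mg: float,
    background_dpm: float = 0.0,
) -> float:
    """Distribution volume in μl per mg protein for one counting channel.

    Both the cell lysate and medium-aliquot counts are background-corrected
    first.  Cell counts at or below background give Vd = 0 (clamped with a
    warning when strictly below); a medium concentration that is not positive
    after correction is rejected — the assay cannot be quantified.
    """
    if aliquot_volume_ul <= 0:
        raise ValueError("aliquot_volume_ul must be > 0")
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    medium_dpm_per_ul = (aliquot_dpm - background_dpm) / aliquot_volume_ul
    if medium_dpm_per_ul <= 0:
        raise ValueError("medium concentration non-positive after background correction")
    cells = cell_dpm - background_dpm
    if cells < 0:
        warnings.warn("cell dpm below background clamped to 0", stacklevel=2)
        cells = 0.0
    return cells / medium_dpm_per_ul / protein_mg


def corrected_vd(substrate_vd: float, marker_vd: float) -> float:
    """Substrate Vd corrected for non-specific binding (marker subtraction).

    Negative values are returned unchanged (flagged by table processing);
    over-correction is a signal, not something to hide.
    """
    return substrate_vd - marker_vd


def pgp_factor_increase(
    test_vds: "list[float] | np.ndarray",
    control_vds: "list[float] | np.ndarray",
) -> FactorIncrease:
    """Ratio of group-mean corrected Vd, inhibitor over control.

    A factor > 1 indicates that blocking the efflux pump raised substrate
    accumulation, i.e. the transporter is functional.  Reported descriptively.
    """
    test = np.asarray(test_vds, dtype=float)
    control = np.asarray(control_vds, dtype=float)
    if test.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_control = float(control.mean())
    if mean_control <= 0:
        raise ValueError("control mean Vd must be > 0")
    mean_test = float(test.mean())
    return FactorIncrease(
        factor=mean_test / mean_control,
        mean_test=mean_test,
        mean_control=mean_control,
        n_test=int(test.size),
        n_control=int(control.size),
    )


def process_uptake_table(
    table: pd.DataFrame,
    substrate_background_dpm: float = 0.0,
    marker_background_dpm: float = 0.0,
) -> tuple[pd.DataFrame, FactorIncrease]:
    """Per-well distribution volumes and the efflux-inhibition factor.

    Expects columns ``well_id, condition, substrate_dpm, marker_dpm,
    substrate_aliquot_dpm, marker_aliquot_dpm, aliquot_ul, protein_mg`` with
    condition in {control, inhibitor}.  Background is a per-plate scalar per
    channel.  Returns the augmented table and the inhibitor/control factor.
    """
    required = {
        "well_id", "condition", "substrate_dpm", "marker_dpm",
        "substrate_aliquot_dpm", "marker_aliquot_dpm", "aliquot_ul", "protein_mg",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"uptake table is missing columns: {sorted(missing)}")
    conditions = set(table["condition"])
    if not conditions <= {"control", "inhibitor"}:
        raise ValueError(f"unknown conditions: {sorted(conditions - {'control', 'inhibitor'})}")

    out = table.copy()
    out["substrate_vd_ul_mg"] = [
        distribution_volume(r.substrate_dpm, r.substrate_aliquot_dpm, r.aliquot_ul,
                            r.protein_mg, substrate_background_dpm)
        for r in out.itertuples()
    ]
    out["marker_vd_ul_mg"] = [
        distribution_volume(r.marker_dpm, r.marker_aliquot_dpm, r.aliquot_ul,
                            r.protein_mg, marker_background_dpm)
        for r in out.itertuples()
    ]
    out["corrected_vd_ul_mg"] = out["substrate_vd_ul_mg"] - out["marker_vd_ul_mg"]
    out["negative_corrected_vd"] = out["corrected_vd_ul_mg"] < 0
    if out["negative_corrected_vd"].any():
        warnings.warn("negative corrected Vd in uptake table (over-correction)", stacklevel=2)

    factor = pgp_factor_increase(
        out.loc[out["condition"] == "inhibitor", "corrected_vd_ul_mg"].to_numpy(),
        out.loc[out["condition"] == "control", "corrected_vd_ul_mg"].to_numpy(),
    )
    return out, factor


def alp_activity(absorbance_405: float, protein_mg: float) -> float:
    """ALP activity as absorbance units per mg protein."""
    if protein_mg <= 0:
        raise ValueError("protein_mg must be > 0")
    return absorbance_405 / protein_mg


def process_alp_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well ALP activities; expects ``well_id, group, absorbance, protein_mg``."""
    required = {"well_id", "group", "absorbance", "protein_mg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ALP table is missing columns: {sorted(missing)}")
    out = table.copy()
    out["activity_au_per_mg"] = [
        alp_activity(r.absorbance, r.protein_mg) for r in out.itertuples()
    ]
    return out


def alp_group_ratio(activities_a: "list[float]", activities_b: "list[float]") -> float:
    """Ratio of mean ALP activity between two groups (e.g. PBEC vs RBE4)."""
    a = np.asarray(activities_a, dtype=float)
    b = np.asarray(activities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if b.mean() == 0:
        raise ValueError("denominator group has zero mean activity")
    return float(a.mean() / b.mean())
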