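"""Relative-standard-curve quantification of TaqMan qPCR data.

Each gene on a plate carries a dilution-series standard curve; Ct is linear in
log10 of template quantity with negative slope, so quantities of unknowns are
read off the fitted line.  Target quantities are normalised by an endogenous
reference gene (e.g. GAPDH) in the same sample:

    NT = target quantity / reference quantity

and conditions are compared as the fold difference NT_test / NT_calibrator.
Quantity units are arbitrary dilution units; they cancel in the fold
difference.  A 2-fold difference (in either direction) is the significance
rule used for batch-stability monitoring.

Amplification efficiency is 10^(−1/slope) − 1: a slope of −3.3219 Ct per
decade is 100% efficiency (one Ct per doubling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ROLES = ("sample", "standard", "ntc", "ext_neg", "rt_neg")
CONTROL_ROLES = ("ntc", "ext_neg", "rt_neg")

#: fold change this large or its reciprocal is called significant
SIGNIFICANT_FOLD = 2.0


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float  # Ct per log10 quantity, < 0
    intercept: float  # Ct at quantity 1
    r_squared: float
    efficiency: float  # 10^(−1/slope) − 1

    def quantity(self, ct: float) -> float:
        """Invert the curve: relative quantity for an observed Ct."""
        if np.isnan(ct):
            return float("nan")
        return float(10.0 ** ((ct - self.intercept) / self.slope))


@dataclass(frozen=True)
class FoldDifference:
    gene: str
    fold: float
    significant: bool
    mean_nt_test: float
    mean_nt_calibrator: float


@dataclass(frozen=True)
class QpcrPlate:
    """Long-format plate: sample wells, standard series and negative controls.

    ``data`` columns: sample_id, gene, replicate, ct, role, quantity (known
    relative quantity, standards only).  Undetected wells carry ct = NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "gene", "replicate", "ct", "role", "quantity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table is missing columns: {sorted(missing)}")
        bad = set(self.data["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        ct = self.data["ct"]
        if (ct.dropna() <= 0).any():
            raise ValueError("detected Ct values must be > 0")

    @property
    def samples(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "sample"]

    @property
    def standards(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "standard"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.data["role"].isin(CONTROL_ROLES)]


def fit_standard_curve(
    quantities: "list[float] | np.ndarray",
    cts: "list[float] | np.ndarray",
    gene: str = "",
) -> StandardCurve:
    """OLS of Ct on log10(quantity); rejects non-negative slopes as failed runs."""
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cts, dtype=float)
    if q.size != c.size:
        raise ValueError("quantities and Ct values differ in length")
    if np.unique(q).size < 2:
        raise ValueError("at least two distinct standard quantities are required")
    if (q <= 0).any():
        raise ValueError("standard quantities must be > 0")
    x = np.log10(q)
    if np.unique(x).size == 2 and x.size == 2:
        slope = float((c[1] - c[0]) / (x[1] - x[0]))
        intercept = float(c[0] - slope * x[0])
        r_squared = 1.0
    else:
        fit = stats.linregress(x, c)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue) ** 2
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative (failed run)")
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        efficiency=float(10.0 ** (-1.0 / slope) - 1.0),
    )


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    """Relative quantity for one (mean) Ct; NaN propagates as undetected."""
    return curve.quantity(ct)


def mean_ct(replicate_cts: "list[float] | np.ndarray") -> float:
    """Aggregate technical replicates by mean Ct, dropping undetected wells.

    All-undetected triplicates return NaN (propagated, with a warning).
    """
    c = np.asarray(replicate_cts, dtype=float)
    detected = c[~np.isnan(c)]
    if detected.size == 0:
        warnings.warn("all replicates undetected; quantity will be missing", stacklevel=2)
        return float("nan")
    if detected.size < c.size:
        warnings.warn("undetected replicate(s) excluded from mean Ct", stacklevel=2)
    return float(detected.mean())


def validate_controls(plate: QpcrPlate, ct_floor: float = 38.0) -> pd.DataFrame:
    """Check the plate's negative controls (NTC, extraction and RT negatives).

    A control is acceptable when undetected or amplifying only above the Ct
    floor.  Returns a per-control table with an ``ok`` column.
    """
    ctrl = plate.controls.copy()
    ctrl["ok"] = ctrl["ct"].isna() | (ctrl["ct"] > ct_floor)
    if not ctrl["ok"].all():
        bad = ctrl.loc[~ctrl["ok"], ["gene", "role", "ct"]]
        warnings.warn(f"negative-control amplification detected:\n{bad}", stacklevel=2)
    return ctrl


def quantify_plate(plate: QpcrPlate, reference_gene: str) -> pd.DataFrame:
    """Per-sample relative quantities and reference-normalised targets (NT).

    Fits one standard curve per gene, averages technical replicates by mean
    Ct, inverts the curve, and divides each target gene's quantity by the
    reference gene's quantity in the same sample.  Returns a long table with
    columns ``sample_id, gene, mean_ct, quantity, nt`` (nt is NaN for the
    reference gene itself).
    """
    genes = sorted(plate.samples["gene"].unique())
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} has no sample wells")
    curves = {}
    for gene in genes:
        std = plate.standards[plate.standards["gene"] == gene]
        if std.empty:
            raise ValueError(f"no standard series for gene {gene!r}")
        curves[gene] = fit_standard_curve(std["quantity"], std["ct"], gene=gene)

    rows = []
    for (sample_id, gene), grp in plate.samples.groupby(["sample_id", "gene"], sort=False):
        mct = mean_ct(grp["ct"].to_numpy())
        rows.append({
            "sample_id": sample_id,
            "gene": gene,
            "mean_ct": mct,
            "quantity": relative_quantity(mct, curves[gene]),
        })
    quant = pd.DataFrame(rows)
    ref = quant[quant["gene"] == reference_gene].set_index("sample_id")["quantity"]
    quant["nt"] = [
        float("nan") if r.gene == reference_gene else r.quantity / ref.get(r.sample_id, float("nan"))
        for r in quant.itertuples()
    ]
    return quant


def normalized_fold_difference(
    nt_test: "list[float] | np.ndarray",
    nt_calibrator: "list[float] | np.ndarray",
    gene: str = "",
) -> FoldDifference:
    """Fold difference NT_test / NT_calibrator with the symmetric 2-fold rule."""
    t = np.asarray(nt_test, dtype=float)
    c = np.asarray(nt_calibrator, dtype=float)
    t, c = t[~np.isnan(t)], c[~np.isnan(c)]
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must contain detected NT values")
    mean_ntc = float(c.mean())
    if mean_ntc <= 0:
        raise ValueError("calibrator NT must be positive")
    fold = float(t.mean()) / mean_ntc
    # boundary-equal folds count as significant; tolerate float round-off there
    tol = 1e-9
    significant = (fold >= SIGNIFICANT_FOLD * (1.0 - tol)
                   or fold <= (1.0 / SIGNIFICANT_FOLD) * (1.0 + tol))
    return FoldDifference(
        gene=gene,
        fold=fold,
        significant=bool(significant),
        mean_nt_test=float(t.mean()),
        mean_nt_calibrator=mean_ntc,
    )
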