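"""Lipophilicity-based permeability screen with transporter-substrate calls.

Compounds crossing the barrier passively show apparent permeability that is
an approximately linear function of calculated octanol–water Log P.  A
reference line is fitted (OLS) over designated passive calibrators only;
every compound is then compared against its prediction:

    residual = observed Papp − predicted Papp

Compounds far enough ABOVE the line are called carrier-mediated uptake
substrates; far enough BELOW, substrates of efflux or active removal; the
rest passive.  "Far enough" is k × the reference residual scale, floored by a
minimum absolute margin proportional to the predicted Papp, because the
reference fit can be nearly exact while biological scatter is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_K = 2.0
DEFAULT_MIN_MARGIN_FRAC = 0.1


@dataclass(frozen=True)
class PassiveLine:
    slope: float  # cm/s per Log P unit
    intercept: float  # cm/s at Log P = 0
    r_squared: float
    residual_scale: float  # residual standard error of the reference fit
    log_scale: bool = False  # True when fitted on log10(Papp)

    def predict(self, logp: "float | np.ndarray") -> "float | np.ndarray":
        pred = self.slope * np.asarray(logp, dtype=float) + self.intercept
        if self.log_scale:
            pred = 10.0 ** pred
        return pred if np.ndim(logp) else float(pred)


def fit_passive_line(compounds: pd.DataFrame, log_scale: bool = False) -> PassiveLine:
    """Fit the passive-permeation reference line over reference compounds only.

    ``compounds`` needs columns ``name, logp, papp_cm_s, is_reference``.  The
    response is Papp, or log10(Papp) with ``log_scale=True`` for screens with
    a wide dynamic range.  ``residual_scale`` is the residual standard error
    (ddof = 2) of the reference fit, or the RMS residual for 2 references.
    """
    refs = compounds[compounds["is_reference"].astype(bool)]
    if len(refs) < 2:
        raise ValueError("at least two reference compounds are required")
    x = refs["logp"].to_numpy(dtype=float)
    y = refs["papp_cm_s"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("reference Log P values are all identical")
    if log_scale:
        if (y <= 0).any():
            raise ValueError("log-scale fit requires strictly positive Papp")
        y = np.log10(y)
    if x.size == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        intercept = float(y[0] - slope * x[0])
        r_squared, residual_scale = 1.0, 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue) ** 2
        resid = y - (slope * x + intercept)
        residual_scale = float(np.sqrt((resid**2).sum() / (x.size - 2)))
        # snap float round-off on an exact fit to a true zero scale
        if residual_scale < 1e-9 * float(np.abs(y).max()):
            residual_scale = 0.0
    return PassiveLine(slope=slope, intercept=intercept, r_squared=r_squared,
                       residual_scale=residual_scale, log_scale=log_scale)


def classification_margin(
    predicted: "float | np.ndarray",
    line: PassiveLine,
    k: float = DEFAULT_K,
    min_margin_frac: float = DEFAULT_MIN_MARGIN_FRAC,
) -> "float | np.ndarray":
    """Outlier threshold at a given prediction: max(k·residual_scale, frac·|pred|)."""
    # 0·∞ guard: an exact reference fit leaves only the absolute-margin floor
    k_term = k * line.residual_scale if line.residual_scale > 0 else 0.0
    return np.maximum(k_term, min_margin_frac * np.abs(predicted))


def classify_transport(
    compounds: pd.DataFrame,
    line: PassiveLine,
    k: float = DEFAULT_K,
    min_margin_frac: float = DEFAULT_MIN_MARGIN_FRAC,
) -> pd.DataFrame:
    """Call each compound passive, uptake (above line) or efflux (below line).

    Residuals are on the fitted scale (linear Papp by default).  Reference
    compounds are classified too, so their residuals stay visible in the
    output.  With a zero residual scale and non-reference compounds present,
    the absolute-margin floor alone is used (warned).
    """
    out = compounds.copy()
    x = out["logp"].to_numpy(dtype=float)
    y = out["papp_cm_s"].to_numpy(dtype=float)
    pred_line = line.slope * x + line.intercept
    if line.log_scale:
        obs = np.log10(y)
        resid = obs - pred_line
        margin = classification_margin(pred_line, line, k, min_margin_frac)
        out["predicted_papp_cm_s"] = 10.0 ** pred_line
    else:
        resid = y - pred_line
        margin = classification_margin(pred_line, line, k, min_margin_frac)
        out["predicted_papp_cm_s"] = pred_line
    if line.residual_scale == 0 and (~out["is_reference"].astype(bool)).any():
        warnings.warn(
            "reference fit is exact; falling back to the absolute-margin rule",
            stacklevel=2,
        )
    out["residual"] = resid
    out["margin"] = margin
    out["transport_class"] = np.select(
        [resid > margin, resid < -margin], ["uptake", "efflux"], default="passive"
    )
    return out
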