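"""Synthetic assay-data generators emulating the study's measurement designs.

Every table the analysis modules consume can be generated here with known
ground truth, so the whole pipeline is testable end-to-end by parameter
recovery: program a permeability, an efflux-inhibition factor, a fold change
or a TEER mean; run the analysis; compare.

The transwell generator integrates the two-compartment mass balance

    dA_R/dt =  Papp·A·(C_D − C_R)
    dA_D/dt = −Papp·A·(C_D − C_R)

exactly (the per-interval ODE is linear, so a closed form is used), with the
receiver compartment replaced by tracer-free buffer at each transfer.  The
donor therefore genuinely depletes; the reported donor concentration is, as
in the bench protocol, measured from a donor sample taken at the end of the
run (``donor_sampling="end"``; a t=0 convention is available).

Counting noise is Poisson on total counts over a fixed counting window
(default 1 min, so dpm and counts coincide); counting efficiency is applied
multiplicatively and background is added before counting.  Inter-insert
permeability variability is lognormal (mean-preserving) with the configured
coefficient of variation.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    COLCHICINE_TRACER,
    SUCROSE_MARKER_TRACER,
    SUCROSE_TRACER,
    InsertGeometry,
    TracerSpec,
    TransferSchedule,
)
from .qpcr import QpcrPlate
from .screen import classification_margin, PassiveLine


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise settings for a transwell simulation."""

    true_papp_cm_s: float
    insert_cv: float = 0.0
    n_inserts: int = 1
    seed: int = 0
    noise_model: str = "poisson"  # {"none", "poisson"}

    def __post_init__(self) -> None:
        if self.true_papp_cm_s < 0:
            raise ValueError("true_papp_cm_s must be >= 0")
        if self.insert_cv < 0:
            raise ValueError("insert_cv must be >= 0")
        if self.n_inserts < 1:
            raise ValueError("n_inserts must be >= 1")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError("noise_model must be 'none' or 'poisson'")


def _lognormal_mean_preserving(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0 or mean == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _count(rng: np.random.Generator, true_dpm_rate: float, noise_model: str,
           window_min: float) -> float:
    """Measured dpm for a true count rate over one counting window."""
    if noise_model == "none":
        return true_dpm_rate
    return float(rng.poisson(true_dpm_rate * window_min)) / window_min


def transwell_interval_amounts(
    papp_cm_s: float,
    geom: InsertGeometry,
    initial_donor_dpm: float,
    schedule: TransferSchedule,
) -> pd.DataFrame:
    """Exact tracer amounts (dpm) per clearance interval, no noise.

    Within an interval the receiver starts tracer-free and the linear
    two-compartment balance has the closed form
    A_R(t) = T·V_R/(V_D+V_R)·(1 − exp(−PS·(1/V_D+1/V_R)·t)) with T the donor
    amount carried into the interval.  Columns: ``time_min, donor_start_dpm,
    receiver_dpm, donor_end_dpm``.
    """
    ps_ul_min = papp_cm_s * geom.area_cm2 * 6e4  # cm³/s → μl/min
    v_d, v_r = geom.donor_volume_ul, geom.receiver_volume_ul
    b = ps_ul_min * (1.0 / v_d + 1.0 / v_r)
    rows = []
    donor = initial_donor_dpm
    for t, dt in zip(schedule.times_min, schedule.interval_durations):
        if ps_ul_min == 0:
            receiver = 0.0
        else:
            receiver = donor * (v_r / (v_d + v_r)) * -np.expm1(-b * dt)
        rows.append({
            "time_min": t,
            "donor_start_dpm": donor,
            "receiver_dpm": receiver,
            "donor_end_dpm": donor - receiver,
        })
        donor -= receiver
    return pd.DataFrame(rows)


def simulate_transwell(
    config: SimulationConfig,
    geom: InsertGeometry = InsertGeometry(),
    tracer: TracerSpec = SUCROSE_TRACER,
    schedule: TransferSchedule = TransferSchedule(),
    donor_sampling: str = "end",
    count_window_min: float = 1.0,
    donor_aliquot_ul: float = 100.0,
) -> pd.DataFrame:
    """Simulate a batch of sequential-receiver-well permeability assays.

    Returns a long table with one row per insert and collection time:
    ``insert_id, time_min, receiver_dpm, donor_dpm_per_ul, background_dpm,
    true_papp_cm_s``.  ``receiver_dpm`` is the raw measured count rate
    (background included); ``donor_dpm_per_ul`` is the background-corrected
    measured donor concentration from a ``donor_aliquot_ul`` sample taken at
    the end of the run (or the t=0 donor with ``donor_sampling="start"``).
    Identical seeds reproduce the table bit-for-bit.
    """
    if donor_sampling not in ("end", "start"):
        raise ValueError("donor_sampling must be 'end' or 'start'")
    rng = np.random.default_rng(config.seed)
    eff = tracer.counting_efficiency
    bg = tracer.background_dpm
    initial_donor = tracer.dpm_per_ul * geom.donor_volume_ul
    papps = _lognormal_mean_preserving(rng, config.true_papp_cm_s, config.insert_cv,
                                       config.n_inserts)
    rows = []
    for i, papp_i in enumerate(papps):
        amounts = transwell_interval_amounts(papp_i, geom, initial_donor, schedule)
        donor_true = (amounts["donor_end_dpm"].iloc[-1] if donor_sampling == "end"
                      else initial_donor)
        donor_conc_true = donor_true / geom.donor_volume_ul
        aliquot_rate = donor_conc_true * donor_aliquot_ul * eff + bg
        aliquot_meas = _count(rng, aliquot_rate, config.noise_model, count_window_min)
        donor_conc_meas = max(aliquot_meas - bg, 0.0) / donor_aliquot_ul
        for rec in amounts.itertuples():
            rate = rec.receiver_dpm * eff + bg
            rows.append({
                "insert_id": f"insert_{i:03d}",
                "time_min": rec.time_min,
                "receiver_dpm": _count(rng, rate, config.noise_model, count_window_min),
                "donor_dpm_per_ul": donor_conc_meas,
                "background_dpm": bg,
                "true_papp_cm_s": papp_i,
            })
    return pd.DataFrame(rows)


def simulate_teer_batch(
    n_inserts: int,
    mean_teer_ohm_cm2: float,
    sd_teer_ohm_cm2: float,
    blank_ohm: float = 120.0,
    geom: InsertGeometry = InsertGeometry(),
    seed: int = 0,
) -> pd.DataFrame:
    """Raw/blank resistance readings whose blank-and-area correction recovers
    a Gaussian TEER batch (truncated at zero: raw never falls below blank)."""
    if n_inserts < 1:
        raise ValueError("n_inserts must be >= 1")
    if mean_teer_ohm_cm2 < 0 or sd_teer_ohm_cm2 < 0:
        raise ValueError("mean and sd must be >= 0")
    rng = np.random.default_rng(seed)
    teer = mean_teer_ohm_cm2 + sd_teer_ohm_cm2 * rng.standard_normal(n_inserts)
    teer = np.clip(teer, 0.0, None)
    return pd.DataFrame({
        "insert_id": [f"insert_{i:03d}" for i in range(n_inserts)],
        "raw_ohm": blank_ohm + teer / geom.area_cm2,
        "blank_ohm": blank_ohm,
        "area_cm2": geom.area_cm2,
    })


def simulate_uptake_plate(
    n_control: int = 6,
    n_test: int = 6,
    vd_control_ul_mg: float = 20.0,
    factor: float = 1.34,
    nonspecific_vd_ul_mg: float = 5.0,
    protein_mg: float = 0.1,
    tracer_pair: tuple[TracerSpec, TracerSpec] = (COLCHICINE_TRACER, SUCROSE_MARKER_TRACER),
    noise_sd: float = 0.0,
    seed: int = 0,
    aliquot_volume_ul: float = 50.0,
) -> pd.DataFrame:
    """Dual-channel uptake plate with a programmable efflux-inhibition effect.

    Control wells carry a specific substrate distribution volume of
    ``vd_control_ul_mg``; inhibitor wells carry ``factor`` times that.  Both
    groups share the extracellular space encoded by ``nonspecific_vd_ul_mg``
    in the marker channel (and added to the substrate channel).  ``noise_sd``
    is the fractional Gaussian measurement noise on cell counts per channel.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if vd_control_ul_mg < 0 or nonspecific_vd_ul_mg < 0:
        raise ValueError("distribution volumes must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    substrate, marker = tracer_pair
    rows = []
    conditions = ["control"] * n_control + ["inhibitor"] * n_test
    for i, condition in enumerate(conditions):
        specific = vd_control_ul_mg * (factor if condition == "inhibitor" else 1.0)
        row = {"well_id": f"well_{i:03d}", "condition": condition,
               "aliquot_ul": aliquot_volume_ul, "protein_mg": protein_mg}
        for prefix, tracer, vd_total in (
            ("substrate", substrate, specific + nonspecific_vd_ul_mg),
            ("marker", marker, nonspecific_vd_ul_mg),
        ):
            conc_meas = tracer.dpm_per_ul * tracer.counting_efficiency  # dpm/μl as counted
            cell_true = vd_total * protein_mg * conc_meas
            cell_meas = cell_true * (1.0 + noise_sd * rng.standard_normal())
            row[f"{prefix}_dpm"] = max(cell_meas, 0.0) + tracer.background_dpm
            row[f"{prefix}_aliquot_dpm"] = conc_meas * aliquot_volume_ul + tracer.background_dpm
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_qpcr_plate(
    true_quantities: Mapping[str, Mapping[str, float]],
    curve_slope: float = -3.3219,
    curve_intercept: float = 25.0,
    n_standards: int = 5,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> QpcrPlate:
    """TaqMan plate with standard curves, technical replicates and controls.

    ``true_quantities`` maps gene → sample_id → true relative quantity.
    Each gene gets a tenfold standard dilution ladder (1, 0.1, …) read off
    the programmed line Ct = intercept + slope·log10(q), and every sample is
    run in ``n_replicates`` technical replicates with Gaussian Ct noise.
    Negative controls (NTC, extraction and RT negatives) are undetected.
    """
    if curve_slope >= 0:
        raise ValueError("curve_slope must be negative (Ct decreases with quantity)")
    if n_standards < 2:
        raise ValueError("n_standards must be >= 2")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)

    def ct_of(q: float) -> float:
        return curve_intercept + curve_slope * np.log10(q)

    rows = []
    for gene, samples in true_quantities.items():
        for j in range(n_standards):
            q = 10.0 ** (-j)
            rows.append({"sample_id": f"std_{j}", "gene": gene, "replicate": 0,
                         "ct": ct_of(q) + replicate_sd * rng.standard_normal(),
                         "role": "standard", "quantity": q})
        for sample_id, q in samples.items():
            if not q > 0:
                raise ValueError("true quantities must be > 0")
            for rep in range(n_replicates):
                rows.append({"sample_id": sample_id, "gene": gene, "replicate": rep,
                             "ct": ct_of(q) + replicate_sd * rng.standard_normal(),
                             "role": "sample", "quantity": np.nan})
        for role in ("ntc", "ext_neg", "rt_neg"):
            rows.append({"sample_id": role, "gene": gene, "replicate": 0,
                         "ct": np.nan, "role": role, "quantity": np.nan})
    return QpcrPlate(pd.DataFrame(rows))


def simulate_alp_plate(
    group_activities_au_mg: Mapping[str, float],
    n_wells: int = 6,
    protein_mg: float = 0.02,
    absorbance_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Endpoint pNPP absorbances for groups with programmed ALP activities."""
    if absorbance_sd < 0:
        raise ValueError("absorbance_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, activity in group_activities_au_mg.items():
        for i in range(n_wells):
            absorbance = activity * protein_mg + absorbance_sd * rng.standard_normal()
            rows.append({"well_id": f"{group}_{i:02d}", "group": group,
                         "absorbance": max(absorbance, 0.0), "protein_mg": protein_mg})
    return pd.DataFrame(rows)


#: passive calibrators of the screen with calculated Log P values
REFERENCE_COMPOUNDS: tuple[tuple[str, float], ...] = (
    ("sucrose", -3.7),
    ("naloxone", 2.1),
    ("propranolol", 3.0),
    ("diazepam", 2.8),
)

#: transporter substrates with their expected deviation from the passive line
OUTLIER_COMPOUNDS: tuple[tuple[str, float, str], ...] = (
    ("leucine", -1.5, "uptake"),
    ("caffeine", -0.07, "uptake"),
    ("digoxin", 1.26, "efflux"),
    ("colchicine", 1.30, "efflux"),
    ("vinblastine", 3.7, "efflux"),
    ("glutamate", -3.7, "efflux"),
)


def simulate_screen_table(
    slope_cm_s_per_logp: float = 4.0e-6,
    intercept_cm_s: float = 2.087e-5,
    ref_noise_sd_cm_s: float = 1.0e-7,
    offset_margins: float = 5.0,
    k: float = 2.0,
    min_margin_frac: float = 0.1,
    reference: tuple[tuple[str, float], ...] = REFERENCE_COMPOUNDS,
    outliers: tuple[tuple[str, float, str], ...] = OUTLIER_COMPOUNDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Compound table for the Log P permeability screen with known classes.

    Reference compounds scatter around the programmed passive line with
    Gaussian noise; transporter substrates are displaced from their predicted
    Papp by ``offset_margins`` classification margins in the direction of
    their class.  The margin uses the same rule as the classifier, with the
    nominal reference noise standing in for the fitted residual scale.

    The default reference noise is kept small relative to the classifier's
    absolute-margin floor (10% of the predicted Papp): with only four
    reference compounds the fitted residual scale is a 2-df estimate whose
    upper tail would otherwise blur programmed offsets, so the default
    screen exercises the classification logic with the floor as the
    operative margin.  Raise ``ref_noise_sd_cm_s`` to study noisy screens.
    """
    if offset_margins < 0:
        raise ValueError("offset_margins must be >= 0")
    rng = np.random.default_rng(seed)
    nominal = PassiveLine(slope=slope_cm_s_per_logp, intercept=intercept_cm_s,
                          r_squared=1.0, residual_scale=ref_noise_sd_cm_s)
    rows = []
    for name, logp in reference:
        pred = nominal.predict(logp)
        papp = pred + ref_noise_sd_cm_s * rng.standard_normal()
        rows.append({"name": name, "logp": logp, "papp_cm_s": max(papp, 1e-8),
                     "is_reference": True, "known_class": "passive"})
    for name, logp, known_class in outliers:
        pred = nominal.predict(logp)
        margin = classification_margin(pred, nominal, k, min_margin_frac)
        sign = 1.0 if known_class == "uptake" else -1.0
        papp = pred + sign * offset_margins * margin
        if papp <= 0:
            raise ValueError(
                f"{name}: programmed offset drives Papp non-positive; reduce offset_margins"
            )
        rows.append({"name": name, "logp": logp, "papp_cm_s": papp,
                     "is_reference": False, "known_class": known_class})
    return pd.DataFrame(rows)
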