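"""Transendothelial electrical resistance (TEER) correction and quality control.

A raw resistance reading across a cell-covered insert includes the resistance
of the filter and coating.  TEER is obtained by subtracting the reading of a
cell-free (blank) coated insert and multiplying by the growth area:

    TEER (Ω·cm²) = (R_raw − R_blank) × A

Monolayers qualify for permeability work only above a TEER floor, and the
barrier must also restrict the paracellular marker: the benchmark used here is
TEER > 500 Ω·cm² together with sucrose Papp < 8×10⁻⁶ cm/s, both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geometry import InsertGeometry


@dataclass(frozen=True)
class QcBenchmark:
    """QC gate for a barrier-competent monolayer (strict inequalities)."""

    min_teer_ohm_cm2: float = 500.0
    max_sucrose_papp_cm_s: float = 8e-6


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    teer_ok: bool
    papp_ok: bool | None  # None when no Papp measurement was supplied


def compute_teer(raw_ohm: float, blank_ohm: float, geom: InsertGeometry) -> float:
    """Blank-corrected, area-normalised TEER in Ω·cm².

    Negative results (raw below blank) are returned as-is; callers flag them
    as degenerate rather than clamping, so measurement problems stay visible.
    """
    if raw_ohm < 0 or blank_ohm < 0:
        raise ValueError("resistances must be non-negative")
    return (raw_ohm - blank_ohm) * geom.area_cm2


def qc_evaluate(
    teer_ohm_cm2: float,
    papp_sucrose_cm_s: float | None = None,
    bench: QcBenchmark = QcBenchmark(),
) -> QcVerdict:
    """Evaluate the QC gate; both criteria are reported separately.

    The permeability criterion is skipped (treated as satisfied) when no
    sucrose Papp is available, e.g. when gating before the flux assay.
    """
    teer_ok = teer_ohm_cm2 > bench.min_teer_ohm_cm2
    papp_ok = None if papp_sucrose_cm_s is None else bool(
        papp_sucrose_cm_s < bench.max_sucrose_papp_cm_s
    )
    return QcVerdict(passed=teer_ok and papp_ok is not False, teer_ok=teer_ok, papp_ok=papp_ok)


def process_teer_table(
    records: pd.DataFrame,
    bench: QcBenchmark = QcBenchmark(),
) -> pd.DataFrame:
    """Apply the blank/area correction and QC gate to a batch of readings.

    Expects columns ``insert_id, raw_ohm, blank_ohm, area_cm2`` (per-insert
    blanks are allowed; a shared blank is simply repeated).  Returns a copy
    with ``teer_ohm_cm2``, ``degenerate`` (negative TEER) and ``qc_teer_pass``
    columns appended.
    """
    required = {"insert_id", "raw_ohm", "blank_ohm", "area_cm2"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"TEER table is missing columns: {sorted(missing)}")
    out = records.copy()
    out["teer_ohm_cm2"] = (out["raw_ohm"] - out["blank_ohm"]) * out["area_cm2"]
    if (out["area_cm2"] <= 0).any():
        raise ValueError("non-positive insert area in TEER table")
    out["degenerate"] = out["teer_ohm_cm2"] < 0
    out["qc_teer_pass"] = out["teer_ohm_cm2"] > bench.min_teer_ohm_cm2
    return out
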