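"""CSV readers/writers and the validated pipeline configuration.

All tables are plain CSV (UTF-8, dot decimal).  Readers validate required
columns up front and raise structured errors naming the file, so malformed
inputs fail before any computation.  The pipeline configuration is a YAML
document validated against a strict schema (unknown keys rejected).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import InsertGeometry
from .qpcr import QpcrPlate
from .teer import QcBenchmark

TEER_COLUMNS = ["insert_id", "raw_ohm", "blank_ohm", "area_cm2"]
CLEARANCE_COLUMNS = ["insert_id", "time_min", "receiver_dpm", "donor_dpm_per_ul",
                     "background_dpm"]
UPTAKE_COLUMNS = ["well_id", "condition", "substrate_dpm", "marker_dpm",
                  "substrate_aliquot_dpm", "marker_aliquot_dpm", "aliquot_ul", "protein_mg"]
ALP_COLUMNS = ["well_id", "group", "absorbance", "protein_mg"]
QPCR_COLUMNS = ["sample_id", "gene", "replicate", "ct", "role", "quantity"]
SCREEN_COLUMNS = ["name", "logp", "papp_cm_s", "is_reference"]


def _read_csv(path: "str | Path", required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_teer_csv(path: "str | Path") -> pd.DataFrame:
    return _read_csv(path, TEER_COLUMNS)


def read_clearance_csv(path: "str | Path") -> pd.DataFrame:
    return _read_csv(path, CLEARANCE_COLUMNS)


def read_uptake_csv(path: "str | Path") -> pd.DataFrame:
    return _read_csv(path, UPTAKE_COLUMNS)


def read_alp_csv(path: "str | Path") -> pd.DataFrame:
    return _read_csv(path, ALP_COLUMNS)


def read_qpcr_csv(path: "str | Path") -> QpcrPlate:
    return QpcrPlate(_read_csv(path, QPCR_COLUMNS))


def read_screen_csv(path: "str | Path") -> pd.DataFrame:
    df = _read_csv(path, SCREEN_COLUMNS)
    df["is_reference"] = df["is_reference"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# --- pipeline configuration ------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    area_cm2: float = 1.13
    donor_volume_ml: float = 0.5
    receiver_volume_ml: float = 1.5

    def build(self) -> InsertGeometry:
        return InsertGeometry(self.area_cm2, self.donor_volume_ml, self.receiver_volume_ml)


class BenchmarkConfig(_Strict):
    min_teer_ohm_cm2: float = 500.0
    max_sucrose_papp_cm_s: float = 8e-6

    def build(self) -> QcBenchmark:
        return QcBenchmark(self.min_teer_ohm_cm2, self.max_sucrose_papp_cm_s)


class TeerGenerator(_Strict):
    n_inserts: int = 91
    mean_teer_ohm_cm2: float = 789.0
    sd_teer_ohm_cm2: float = 171.7
    blank_ohm: float = 120.0


class TranswellGenerator(_Strict):
    true_papp_cm_s: float = 6.07e-6
    insert_cv: float = 0.0
    n_inserts: int = 12
    noise_model: str = "poisson"
    donor_sampling: str = "end"
    count_window_min: float = 1.0


class UptakeGenerator(_Strict):
    n_control: int = 6
    n_test: int = 6
    vd_control_ul_mg: float = 20.0
    factor: float = 1.34
    nonspecific_vd_ul_mg: float = 5.0
    protein_mg: float = 0.1
    noise_sd: float = 0.05


class AlpGenerator(_Strict):
    group_activities_au_mg: dict[str, float] = Field(
        default_factory=lambda: {"PBEC": 25.0, "RBE4": 1.25})
    n_wells: int = 6
    protein_mg: float = 0.02
    absorbance_sd: float = 0.0


class QpcrGenerator(_Strict):
    gene_folds: dict[str, float] = Field(
        default_factory=lambda: {"BCRP": 1.5, "occludin": 1.2, "claudin5": 1.1})
    reference_gene: str = "GAPDH"
    n_samples_per_group: int = 6
    replicate_sd: float = 0.15
    curve_slope: float = -3.3219
    curve_intercept: float = 25.0
    n_standards: int = 5


class ScreenGenerator(_Strict):
    slope_cm_s_per_logp: float = 4.0e-6
    intercept_cm_s: float = 2.087e-5
    ref_noise_sd_cm_s: float = 0.3e-6
    offset_margins: float = 5.0


class AssaySection(_Strict):
    """One assay's input: an existing CSV, or a generator block, or absent."""

    path: Optional[str] = None


class TeerSection(AssaySection):
    simulate: Optional[TeerGenerator] = None


class PermeabilitySection(AssaySection):
    simulate: Optional[TranswellGenerator] = None
    through_origin: bool = False


class UptakeSection(AssaySection):
    simulate: Optional[UptakeGenerator] = None
    substrate_background_dpm: float = 0.0
    marker_background_dpm: float = 0.0


class AlpSection(AssaySection):
    simulate: Optional[AlpGenerator] = None


class QpcrSection(AssaySection):
    simulate: Optional[QpcrGenerator] = None
    reference_gene: str = "GAPDH"
    test_prefix: str = "test"
    calibrator_prefix: str = "calib"


class ScreenSection(AssaySection):
    simulate: Optional[ScreenGenerator] = None
    k: float = 2.0
    min_margin_frac: float = 0.1
    log_scale: bool = False


class PipelineConfig(_Strict):
    output_dir: str = "pipeline_out"
    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    benchmark: BenchmarkConfig = Field(default_factory=BenchmarkConfig)
    teer: Optional[TeerSection] = None
    permeability: Optional[PermeabilitySection] = None
    uptake: Optional[UptakeSection] = None
    alp: Optional[AlpSection] = None
    qpcr: Optional[QpcrSection] = None
    screen: Optional[ScreenSection] = None


def load_config(path: "str | Path") -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
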