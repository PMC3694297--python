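"""Physical descriptions of the transwell assay: insert geometry, radiotracers
and the sequential receiver-well sampling schedule.

Unit conventions used throughout the package: times in minutes, volumes in
microlitres internally (geometry is entered in the conventional ml/cm²),
radioactivity in dpm, permeability in cm/s.  Conversion to cm³/s happens only
when a PS product is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: disintegrations per minute per microcurie (exact by definition of the Ci)
DPM_PER_UCI: float = 2.22e6


@dataclass(frozen=True)
class InsertGeometry:
    """Dimensions of a Transwell filter insert and its two compartments.

    Defaults are a 12-well format insert: 1.13 cm² growth area, 0.5 ml apical
    (donor) buffer and 1.5 ml basal (receiver) buffer.
    """

    area_cm2: float = 1.13
    donor_volume_ml: float = 0.5
    receiver_volume_ml: float = 1.5

    def __post_init__(self) -> None:
        for name in ("area_cm2", "donor_volume_ml", "receiver_volume_ml"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def donor_volume_ul(self) -> float:
        return self.donor_volume_ml * 1000.0

    @property
    def receiver_volume_ul(self) -> float:
        return self.receiver_volume_ml * 1000.0


@dataclass(frozen=True)
class TracerSpec:
    """A radiolabelled tracer as dosed into an assay.

    ``activity_uci_per_ml`` is the activity concentration in the donor or
    uptake medium; ``specific_activity_mci_per_mmol`` links radioactivity to
    chemical amount; ``counting_efficiency`` is the fraction of true
    disintegrations registered by the counter; ``background_dpm`` is the
    instrument background per counting window.
    """

    label: str
    activity_uci_per_ml: float
    specific_activity_mci_per_mmol: float = 1.0
    counting_efficiency: float = 1.0
    background_dpm: float = 0.0

    def __post_init__(self) -> None:
        if not self.activity_uci_per_ml > 0:
            raise ValueError("activity_uci_per_ml must be > 0")
        if not self.specific_activity_mci_per_mmol > 0:
            raise ValueError("specific_activity_mci_per_mmol must be > 0")
        if not 0 < self.counting_efficiency <= 1:
            raise ValueError("counting_efficiency must be in (0, 1]")
        if self.background_dpm < 0:
            raise ValueError("background_dpm must be >= 0")

    @property
    def dpm_per_ul(self) -> float:
        """True tracer concentration in dpm/μl (before counting efficiency)."""
        return self.activity_uci_per_ml * DPM_PER_UCI / 1000.0


#: [14C]sucrose as dosed for the paracellular-permeability QC assay
SUCROSE_TRACER = TracerSpec(
    label="[14C]sucrose",
    activity_uci_per_ml=0.15,
    specific_activity_mci_per_mmol=643.0,
)

#: [3H]colchicine, the P-gp substrate of the uptake assay
COLCHICINE_TRACER = TracerSpec(
    label="[3H]colchicine",
    activity_uci_per_ml=1.0,
    specific_activity_mci_per_mmol=76.5e3,  # 76.5 Ci/mmol
)

#: [14C]sucrose as the extracellular marker channel of the uptake assay
SUCROSE_MARKER_TRACER = TracerSpec(
    label="[14C]sucrose-marker",
    activity_uci_per_ml=0.045,
    specific_activity_mci_per_mmol=0.2e-3,  # 0.2 mCi/mol, as specified per assay
)


@dataclass(frozen=True)
class TransferSchedule:
    """Times (min) at which the insert is moved to a fresh receiver well.

    Each transfer collects the receiver well accumulated since the previous
    transfer, so every sample time closes one clearance interval.
    """

    times_min: tuple[float, ...] = (5.0, 15.0, 30.0)

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_min)
        if len(times) == 0:
            raise ValueError("schedule must contain at least one sample time")
        if times[0] <= 0:
            raise ValueError("first sample time must be > 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "times_min", times)

    @property
    def interval_durations(self) -> tuple[float, ...]:
        starts = (0.0,) + self.times_min[:-1]
        return tuple(t - s for s, t in zip(starts, self.times_min))
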