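"""Core record types shared by every pipeline stage.

Concentrations are micrograms per millilitre throughout; haematocrit is a volume
fraction in (0, 1). Input readers accept haematocrit expressed in percent (values
in (1, 100] are divided by 100) because clinical sources mix the two conventions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ConfigError, DataValidationError


class Analyte(enum.Enum):
    """The two analytes of a parent-drug / metabolite study.

    Display labels default to the lamotrigine study this pipeline was built
    around (parent "LTG", its N2-glucuronide "LTG-N2-GLU").
    """

    PARENT = "PARENT"
    METABOLITE = "METABOLITE"

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {Analyte.PARENT: "LTG", Analyte.METABOLITE: "LTG-N2-GLU"}


class Timepoint(enum.Enum):
    TROUGH = "TROUGH"
    PEAK = "PEAK"


def coerce_hct(value: float) -> float:
    """Normalise a haematocrit to a fraction.

    Values in (1, 100] are interpreted as percent and divided by 100.
    """
    v = float(value)
    if 1.0 < v <= 100.0:
        v /= 100.0
    return v


@dataclass(frozen=True)
class PairedMeasurement:
    """One subject x analyte x timepoint record.

    ``c_b`` is the whole-blood (DBS) concentration; ``c_pl`` the paired plasma
    concentration and ``hct`` the subject's haematocrit, both optional because
    trough-only tables carry blood concentrations alone.
    """

    subject_id: str
    analyte: Analyte
    timepoint: Timepoint
    c_b: float
    c_pl: float | None = None
    hct: float | None = None

    def __post_init__(self) -> None:
        if self.c_b < 0:
            raise DataValidationError(f"c_b must be >= 0, got {self.c_b}")
        if self.c_pl is not None and self.c_pl < 0:
            raise DataValidationError(f"c_pl must be >= 0, got {self.c_pl}")
        if self.hct is not None and not (0.0 < self.hct < 1.0):
            raise DataValidationError(
                f"hct must be a fraction in (0, 1), got {self.hct}"
            )

    @property
    def complete(self) -> bool:
        """True when blood, plasma and haematocrit are all present."""
        return self.c_pl is not None and self.hct is not None


@dataclass(frozen=True)
class CalibrationObservation:
    """A single calibration-standard response: analyte/IS peak-area ratio at a
    nominal concentration, tagged with validation day, matrix lot and replicate."""

    analyte: Analyte
    nominal_conc: float
    response_ratio: float
    day: int = 1
    lot: str = "lot1"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.nominal_conc < 0:
            raise DataValidationError(
                f"nominal_conc must be >= 0 (0 only for blanks), got {self.nominal_conc}"
            )
        if self.response_ratio < 0:
            raise DataValidationError(
                f"response_ratio must be >= 0, got {self.response_ratio}"
            )


#: The 11 calibration levels of the assay, µg/mL.
CAL_LEVELS: tuple[float, ...] = (
    0.1, 0.25, 0.5, 0.75, 1.0, 5.0, 7.5, 10.0, 12.5, 17.5, 20.0,
)

#: Low / medium / high quality-control levels, µg/mL.
QC_LEVELS: tuple[float, ...] = (0.3, 3.0, 15.0)


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and design constants.

    ``acceptance_bias_cv_pct`` is the +/-15 % accuracy/precision acceptance band
    (20 % at the LLOQ per the bioanalytical guidelines); ``matrix_slope_rsd_pct``
    the relative-matrix-effect bound on calibration-slope RSD.
    """

    lloq: float = 0.1
    cal_levels: tuple[float, ...] = CAL_LEVELS
    qc_levels: tuple[float, ...] = QC_LEVELS
    acceptance_bias_cv_pct: float = 15.0
    lloq_bias_cv_pct: float = 20.0
    matrix_slope_rsd_pct: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ConfigError("lloq must be > 0")
        if abs(min(self.cal_levels) - self.lloq) > 1e-12:
            raise ConfigError(
                f"lloq ({self.lloq}) must equal the smallest calibration level "
                f"({min(self.cal_levels)})"
            )
        for name in ("acceptance_bias_cv_pct", "lloq_bias_cv_pct", "matrix_slope_rsd_pct"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("cal_levels", "qc_levels"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)
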