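"""CSV readers and writers for the pipeline's tabular interchange formats.

All tables are comma-separated UTF-8 with a mandatory header row and "." as the
decimal separator. Missing plasma concentration or haematocrit is an empty cell,
never 0. Haematocrit given in percent (values in (1, 100]) is coerced to a
fraction on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import (
    Analyte,
    CalibrationObservation,
    PairedMeasurement,
    Timepoint,
    coerce_hct,
)
from .errors import DataValidationError, SchemaError

PAIRED_COLUMNS = ("subject_id", "analyte", "timepoint", "c_b", "c_pl", "hct")
CALIBRATION_COLUMNS = (
    "analyte", "nominal_conc", "response_ratio", "day", "lot", "replicate",
)
TROUGH_COLUMNS = ("subject_id", "dose", "parent_conc", "metabolite_conc")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _parse_analyte(token: str, row: int) -> Analyte:
    t = str(token).strip().upper()
    for a in Analyte:
        if t in (a.value, a.label.upper()):
            return a
    raise DataValidationError(f"row {row}: unknown analyte '{token}'")


def read_paired_table(path: str | Path) -> list[PairedMeasurement]:
    """Read a paired-measurement CSV into validated records, preserving row order.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`DataValidationError` (with the offending row number, 1-based data
    rows) when a value violates a domain invariant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PAIRED_COLUMNS, path)
    records: list[PairedMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        c_pl = None if pd.isna(row.c_pl) else float(row.c_pl)
        hct = None if pd.isna(row.hct) else coerce_hct(row.hct)
        try:
            records.append(
                PairedMeasurement(
                    subject_id=str(row.subject_id),
                    analyte=_parse_analyte(row.analyte, i),
                    timepoint=Timepoint(str(row.timepoint).strip().upper()),
                    c_b=float(row.c_b),
                    c_pl=c_pl,
                    hct=hct,
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: row {i}: {exc}") from exc
        except ValueError as exc:
            raise DataValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_paired_table(records: Sequence[PairedMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "analyte": [r.analyte.value for r in records],
            "timepoint": [r.timepoint.value for r in records],
            "c_b": [r.c_b for r in records],
            "c_pl": [r.c_pl for r in records],
            "hct": [r.hct for r in records],
        }
    )
    # %.17g keeps write/read a float identity
    df.to_csv(path, index=False, float_format="%.17g")


def read_calibration_table(path: str | Path) -> list[CalibrationObservation]:
    """Read calibration/QC responses (analyte/IS area ratios by level, day, lot)."""
    df = pd.read_csv(path)
    _require_columns(df, CALIBRATION_COLUMNS, path)
    out: list[CalibrationObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                CalibrationObservation(
                    analyte=_parse_analyte(row.analyte, i),
                    nominal_conc=float(row.nominal_conc),
                    response_ratio=float(row.response_ratio),
                    day=int(row.day),
                    lot=str(row.lot),
                    replicate=int(row.replicate),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_calibration_table(
    obs: Sequence[CalibrationObservation], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "analyte": [o.analyte.value for o in obs],
            "nominal_conc": [o.nominal_conc for o in obs],
            "response_ratio": [o.response_ratio for o in obs],
            "day": [o.day for o in obs],
            "lot": [o.lot for o in obs],
            "replicate": [o.replicate for o in obs],
        }
    ).to_csv(path, index=False)


def read_trough_table(path: str | Path) -> pd.DataFrame:
    """Read a per-subject trough table (subject_id, dose, parent_conc, metabolite_conc)."""
    df = pd.read_csv(path)
    _require_columns(df, TROUGH_COLUMNS, path)
    bad = df.index[(df["parent_conc"] <= 0) | (df["metabolite_conc"] < 0)]
    if len(bad):
        raise DataValidationError(
            f"{path}: row {bad[0] + 1}: concentrations must be positive "
            "(parent) / non-negative (metabolite)"
        )
    return df


def trough_to_paired(df: pd.DataFrame) -> list[PairedMeasurement]:
    """Expand a trough table into per-analyte blood-only records (two per subject)."""
    records: list[PairedMeasurement] = []
    for row in df.itertuples(index=False):
        for analyte, col in (
            (Analyte.PARENT, "parent_conc"),
            (Analyte.METABOLITE, "metabolite_conc"),
        ):
            records.append(
                PairedMeasurement(
                    subject_id=str(row.subject_id),
                    analyte=analyte,
                    timepoint=Timepoint.TROUGH,
                    c_b=float(getattr(row, col)),
                )
            )
    return records
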