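"""Concentration tables: data model, CSV I/O, and the built-in printed
summary fixtures.

The pipeline's unit of raw input is a long-form table of per-sample analyte
concentrations in µg/kg wet weight, one row per (sample, analyte). Summary
fixtures transcribe the published per-group statistics (all samples, by fish
species, by cooking method) and are the calibration targets for the
synthetic generator when no raw data are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import analytes

#: Column names of the canonical long-form concentration CSV.
COLUMNS = ("sample_id", "species", "cooking", "replicate", "analyte", "concentration")

#: Concentration unit used throughout; everything downstream assumes it.
UNIT = "ug/kg wet weight"

#: Species sampled in the source surveillance study. Open enum: other labels
#: pass through with a warning so the tool generalises to other surveys.
KNOWN_SPECIES = frozenset(
    {"carp", "caspian_kutum", "caspian_sea_sprat", "starry_sturgeon", "trout"}
)

#: Cooking/preparation methods of the source study. Open enum, as above.
KNOWN_COOKING = frozenset(
    {"raw", "charcoal_grilled", "gas_oven_grilled", "fried"}
)

FIXTURE_NAMES = ("table2_all", "table3_by_species", "table4_by_cooking")

_FIXTURE_FILES = {
    "table2_all": "table2_all.csv",
    "table3_by_species": "table3_by_species.csv",
    "table4_by_cooking": "table4_by_cooking.csv",
}


class SchemaError(ValueError):
    """A required column is missing or the header cannot be interpreted."""


class ValidationError(ValueError):
    """A data row violates the table invariants; carries the row number."""


@dataclass
class ConcentrationTable:
    """Long-form per-sample analyte concentrations.

    Attributes
    ----------
    data
        DataFrame with columns :data:`COLUMNS`; one row per
        (sample_id, analyte), concentrations in µg/kg wet weight.
    unit
        Fixed measurement unit shared by all records.
    """

    data: pd.DataFrame
    unit: str = UNIT

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        conc = pd.to_numeric(df["concentration"], errors="coerce").astype(float)
        bad = df.index[~np.isfinite(conc) | (conc < 0)]
        if len(bad):
            row = int(bad[0])
            raise ValidationError(
                f"row {row}: concentration {df.loc[row, 'concentration']!r} "
                "is not a non-negative number"
            )
        df["concentration"] = conc.astype(float)
        rep = pd.to_numeric(df["replicate"], errors="coerce")
        if (rep.isna() | (rep < 1) | (rep != rep.round())).any():
            row = int(df.index[rep.isna() | (rep < 1) | (rep != rep.round())][0])
            raise ValidationError(f"row {row}: replicate must be a positive integer")
        df["replicate"] = rep.astype(int)
        try:
            df["analyte"] = [analytes.resolve(a) for a in df["analyte"]]
        except analytes.UnknownAnalyteError as exc:
            # re-raise with the offending row number for diagnosability
            for i, a in enumerate(df["analyte"]):
                try:
                    analytes.resolve(a)
                except analytes.UnknownAnalyteError:
                    raise ValidationError(f"row {i}: {exc.args[0]}") from exc
            raise
        dup = df.duplicated(subset=["sample_id", "analyte"])
        if dup.any():
            row = int(df.index[dup][0])
            raise ValidationError(
                f"row {row}: duplicate (sample_id, analyte) pair "
                f"({df.loc[row, 'sample_id']!r}, {df.loc[row, 'analyte']!r})"
            )
        for col, known in (("species", KNOWN_SPECIES), ("cooking", KNOWN_COOKING)):
            unknown = sorted(set(df[col].astype(str)) - known - {"all"})
            if unknown:
                warnings.warn(
                    f"non-canonical {col} label(s): {', '.join(unknown)}",
                    stacklevel=3,
                )

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        return self.unit == other.unit and self.data.equals(other.data)


def read_concentration_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ConcentrationTable:
    """Read a long-form concentration CSV into a validated table.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, ``.`` decimal point.
    column_map
        Optional mapping from the file's column names to the canonical
        names in :data:`COLUMNS`, for foreign headers.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return ConcentrationTable(df)


def write_concentration_csv(table: ConcentrationTable, path: str | Path) -> Path:
    """Write a table to CSV such that reading it back is the identity."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty concentration table")
    path = Path(path)
    # repr-precision floats so the round trip is bit-exact
    table.data.to_csv(path, index=False)
    return path


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the built-in printed summary tables.

    Parameters
    ----------
    name
        ``table2_all`` (pooled over all samples), ``table3_by_species``
        or ``table4_by_cooking``.

    Returns
    -------
    DataFrame with columns ``species, cooking, analyte, mean, median, min,
    max, sd, n`` — one row per group × analyte, analytes including the
    ``TOTAL`` (Σ16 PAH) and ``PAH4`` aggregates. Per-cell sample counts were
    not published, so ``n`` is NaN.
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; choose from {', '.join(FIXTURE_NAMES)}"
        ) from None
    with resources.files("pahrisk.data").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh)
    df["analyte"] = [analytes.resolve(a, allow_aggregates=True) for a in df["analyte"]]
    df["n"] = float("nan")
    return df
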