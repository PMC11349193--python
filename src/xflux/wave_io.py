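"""Reading, validating, merging and normalizing Agilent Wave rate exports.

A Wave "Rate" export is a long-format table with one row per well per
measurement cycle, carrying the columns ``Measurement, Well, Group, Time,
OCR, ECAR`` (optionally ``PER``).  The Group column must follow the
``"<exp_group> <ASSAY>"`` convention — the experimental group name followed
by the assay type (``MITO`` or ``GLYCO``), separated by whitespace — so the
reader can infer both the biological grouping and which stress test a well
belongs to.  Wells labelled with the background group (default
``"Background"``) are instrument blanks and are excluded from analysis but
counted in the read report.

The canonical in-memory container is :class:`RateTable`, a thin wrapper
around a pandas DataFrame with one row per :data:`RATE_COLUMNS` record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    EmptyDirectoryError,
    EmptyFileError,
    MalformedGroupError,
    PlateCollisionError,
    SchemaError,
    StateError,
    ValidationError,
)

#: Canonical column order of a RateTable's underlying DataFrame.
RATE_COLUMNS = (
    "plate_id",
    "well",
    "group_label",
    "exp_group",
    "assay_type",
    "measurement",
    "time_min",
    "ocr",
    "ecar",
    "per",
)

#: Required Wave export columns (canonical lower-case names).
_REQUIRED = ("measurement", "well", "group", "time", "ocr", "ecar")
_OPTIONAL = ("per",)

DEFAULT_BACKGROUND_LABEL = "Background"


@dataclass
class ReadReport:
    """Bookkeeping produced while reading rate files.

    ``background_rows`` maps plate_id -> number of rows dropped because their
    Group equalled the background label; ``missing_cells`` maps plate_id ->
    number of blank OCR/ECAR cells that became flagged NaN values.
    """

    background_rows: dict[str, int] = field(default_factory=dict)
    missing_cells: dict[str, int] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def merge(self, other: "ReadReport") -> "ReadReport":
        out = ReadReport(
            dict(self.background_rows),
            dict(self.missing_cells),
            list(self.messages),
        )
        out.background_rows.update(other.background_rows)
        out.missing_cells.update(other.missing_cells)
        out.messages.extend(other.messages)
        return out

    @property
    def n_background_rows(self) -> int:
        return sum(self.background_rows.values())


@dataclass
class RateTable:
    """Long-format per-well, per-measurement OCR/ECAR records.

    Attributes
    ----------
    data:
        DataFrame with columns :data:`RATE_COLUMNS`.
    normalized:
        Whether rates have been divided by a per-well quantity.
    norm_unit:
        Human-readable unit suffix when ``normalized`` (e.g. ``"per 1e3 cells"``).
    report:
        Read/normalization bookkeeping.
    """

    data: pd.DataFrame
    normalized: bool = False
    norm_unit: str | None = None
    report: ReadReport = field(default_factory=ReadReport)

    def __post_init__(self) -> None:
        missing = [c for c in RATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"RateTable data lacks columns: {missing}")
        if self.normalized and not self.norm_unit:
            raise ValidationError("normalized RateTable requires norm_unit")

    @property
    def plates(self) -> list[str]:
        """Sorted plate manifest."""
        return sorted(self.data["plate_id"].unique())

    @property
    def assay_types(self) -> list[str]:
        return sorted(self.data["assay_type"].unique())

    @property
    def n_measurements(self) -> int:
        return int(self.data["measurement"].max())

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> Path:
        """Export the merged table as canonical long-format CSV."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path


@dataclass
class NormalizationTable:
    """Per-well or per-group quantities (cell counts or µg protein).

    Entries are ``(plate_id, well-or-group key, quantity, unit)``; well-level
    entries take precedence over group-level entries.  ``unit`` is ``"cells"``
    or ``"ug_protein"``.
    """

    entries: pd.DataFrame  # columns: plate_id, well, group, quantity, unit

    def __post_init__(self) -> None:
        df = self.entries
        need = {"plate_id", "quantity", "unit"}
        if not need.issubset(df.columns):
            raise SchemaError(
                f"normalization table needs columns {sorted(need)}; found {list(df.columns)}"
            )
        for col in ("well", "group"):
            if col not in df.columns:
                df[col] = pd.NA
        if (df["quantity"] <= 0).any() or df["quantity"].isna().any():
            raise ValidationError("normalization quantities must be positive")
        bad_units = set(df["unit"].unique()) - {"cells", "ug_protein"}
        if bad_units:
            raise ValidationError(f"unknown normalization units: {sorted(bad_units)}")
        key = df["plate_id"].astype(str) + "|" + df["well"].fillna("").astype(str) + "|" + df[
            "group"
        ].fillna("").astype(str)
        if key.duplicated().any():
            dupes = sorted(key[key.duplicated()].unique())
            raise ValidationError(f"duplicate normalization entries for keys: {dupes}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormalizationTable":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df)

    @property
    def unit(self) -> str:
        units = set(self.entries["unit"].unique())
        if len(units) != 1:
            raise ValidationError(f"mixed normalization units: {sorted(units)}")
        return units.pop()


def parse_group_label(label: str, *, source: str | None = None) -> tuple[str, str]:
    """Split a Wave Group label into ``(exp_group, assay_type)``.

    The split happens on the LAST run of whitespace so experimental group
    names may themselves contain spaces: ``"wt clone 3 glyco"`` ->
    ``("wt clone 3", "GLYCO")``.  The assay token is upper-cased.
    """
    stripped = label.strip() if isinstance(label, str) else ""
    m = re.match(r"^(.*\S)\s+(\S+)$", stripped, flags=re.DOTALL)
    if m is None:
        where = f" in {source}" if source else ""
        raise MalformedGroupError(
            f"Group label {label!r}{where} must be '<exp_group> <ASSAY>' "
            "(two or more whitespace-separated tokens)"
        )
    return m.group(1), m.group(2).upper()


def _match_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical names to actual headers, tolerating unit suffixes.

    ``"OCR (pmol/min)"`` matches ``ocr``; matching is case-insensitive and a
    canonical name must be the first word of the header.
    """
    found: dict[str, str] = {}
    for canonical in _REQUIRED + _OPTIONAL:
        for col in columns:
            head = str(col).strip().lower()
            if head == canonical or re.match(rf"^{canonical}(?![a-z0-9])", head):
                found.setdefault(canonical, col)
    return found


def _exact_float(series: pd.Series) -> pd.Series:
    """Correctly-rounded numeric conversion; blanks/non-numbers become NaN."""

    def conv(v):
        if v is None:
            return np.nan
        if isinstance(v, str):
            v = v.strip()
            if not v:
                return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def _pick_rate_sheet(xls: pd.ExcelFile, sheet: str | None) -> str:
    if sheet is not None:
        if sheet not in xls.sheet_names:
            raise SchemaError(f"sheet {sheet!r} not in workbook (has {xls.sheet_names})")
        return sheet
    for name in xls.sheet_names:
        if "rate" in name.lower():
            return name
    return xls.sheet_names[0]


def read_rate_file(
    path: str | Path,
    plate_id: str | None = None,
    *,
    sheet: str | None = None,
    background_label: str = DEFAULT_BACKGROUND_LABEL,
) -> RateTable:
    """Read one Wave rate export (xlsx) or equivalent CSV into a RateTable.

    Background-group rows are excluded and counted in the read report; blank
    OCR/ECAR cells become flagged NaN values rather than dropped rows.
    """
    path = Path(path)
    if plate_id is None:
        plate_id = path.stem
    if path.suffix.lower() == ".csv":
        raw = pd.read_csv(path, float_precision="round_trip")
    else:
        with pd.ExcelFile(path, engine="openpyxl") as xls:
            # dtype=object defers numeric conversion to _exact_float below;
            # pandas' fast inference parser is not correctly rounded
            raw = xls.parse(_pick_rate_sheet(xls, sheet), dtype=object)

    colmap = _match_columns(list(raw.columns))
    missing = [c for c in _REQUIRED if c not in colmap]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found headers {list(raw.columns)}"
        )
    if len(raw) == 0:
        raise EmptyFileError(f"{path}: rate sheet has zero data rows")

    df = pd.DataFrame(
        {
            "well": raw[colmap["well"]].astype(str).str.strip(),
            "group_label": raw[colmap["group"]].astype(str).str.strip(),
            "measurement": _exact_float(raw[colmap["measurement"]]),
            "time_min": _exact_float(raw[colmap["time"]]),
            "ocr": _exact_float(raw[colmap["ocr"]]),
            "ecar": _exact_float(raw[colmap["ecar"]]),
            "per": (
                _exact_float(raw[colmap["per"]]) if "per" in colmap else np.nan
            ),
        }
    )

    report = ReadReport()
    is_bg = df["group_label"].str.casefold() == background_label.casefold()
    if is_bg.any():
        report.background_rows[plate_id] = int(is_bg.sum())
        df = df.loc[~is_bg].copy()
    if len(df) == 0:
        raise EmptyFileError(f"{path}: no experimental rows after background exclusion")

    parsed = {
        lab: parse_group_label(lab, source=str(path))
        for lab in df["group_label"].unique()
    }
    df["exp_group"] = df["group_label"].map(lambda s: parsed[s][0])
    df["assay_type"] = df["group_label"].map(lambda s: parsed[s][1])
    df["plate_id"] = plate_id

    if df["measurement"].isna().any() or (df["measurement"] < 1).any():
        raise SchemaError(f"{path}: Measurement values must be integers >= 1")
    df["measurement"] = df["measurement"].astype(int)

    dup = df.duplicated(subset=["plate_id", "well", "assay_type", "measurement"])
    if dup.any():
        rows = df.loc[dup, ["well", "measurement"]].head(5).to_dict("records")
        raise SchemaError(f"{path}: duplicate (well, measurement) rows, e.g. {rows}")

    n_missing = int(df["ocr"].isna().sum() + df["ecar"].isna().sum())
    if n_missing:
        report.missing_cells[plate_id] = n_missing
        report.messages.append(f"{plate_id}: {n_missing} blank OCR/ECAR cell(s) flagged")

    df = df[list(RATE_COLUMNS)].sort_values(
        ["plate_id", "well", "assay_type", "measurement"], kind="stable"
    )
    return RateTable(df.reset_index(drop=True), report=report)


def read_data(
    directory: str | Path,
    normalize: NormalizationTable | None = None,
    *,
    pattern: tuple[str, ...] = ("*.xlsx", "*.csv"),
    sheet: str | None = None,
    background_label: str = DEFAULT_BACKGROUND_LABEL,
) -> RateTable:
    """Read every rate file in ``directory`` into one merged RateTable.

    plate_id defaults to the file stem and doubles as the biological-replicate
    grouping factor downstream.  Record order is deterministic
    (plate_id, well, measurement) regardless of filesystem enumeration order.
    """
    directory = Path(directory)
    files = sorted(
        {p for pat in pattern for p in directory.rglob(pat) if p.is_file()},
        key=lambda p: (p.stem, str(p)),
    )
    if not files:
        raise EmptyDirectoryError(f"no rate files matching {pattern} under {directory}")

    seen: dict[str, Path] = {}
    tables: list[RateTable] = []
    for f in files:
        if f.stem in seen:
            raise PlateCollisionError(
                f"duplicate plate_id {f.stem!r}: {seen[f.stem]} and {f}"
            )
        seen[f.stem] = f
        tables.append(read_rate_file(f, sheet=sheet, background_label=background_label))

    report = ReadReport()
    for t in tables:
        report = report.merge(t.report)
    merged = pd.concat([t.data for t in tables], ignore_index=True)
    merged = merged.sort_values(
        ["plate_id", "well", "assay_type", "measurement"], kind="stable"
    ).reset_index(drop=True)
    table = RateTable(merged, report=report)
    if normalize is not None:
        table = normalize_rates(table, normalize)
    return table


def _norm_lookup(norm: NormalizationTable) -> tuple[Mapping, Mapping]:
    df = norm.entries
    by_well = {
        (r.plate_id, r.well): r.quantity
        for r in df.itertuples()
        if pd.notna(r.well) and str(r.well) != ""
    }
    by_group = {
        (r.plate_id, r.group): r.quantity
        for r in df.itertuples()
        if pd.notna(r.group) and str(r.group) != ""
    }
    return by_well, by_group


def normalize_rates(
    table: RateTable,
    norm: NormalizationTable,
    scale: float | None = None,
) -> RateTable:
    """Divide every rate by (quantity / scale) for its well.

    Default scale keeps normalized magnitudes near raw ones: 1000 for cell
    counts (rates per 1e3 cells) and 1 for µg protein (rates per µg).
    Normalizing an already-normalized table raises :class:`StateError`.
    """
    if table.normalized:
        raise StateError("RateTable is already normalized")
    unit = norm.unit
    if scale is None:
        scale = 1000.0 if unit == "cells" else 1.0
    if scale <= 0:
        raise ValidationError("scale must be positive")

    by_well, by_group = _norm_lookup(norm)
    df = table.data.copy()
    keys = list(zip(df["plate_id"], df["well"]))
    gkeys = list(zip(df["plate_id"], df["exp_group"]))
    quantities = np.empty(len(df))
    unmatched: list[tuple[str, str]] = []
    for i, (wk, gk) in enumerate(zip(keys, gkeys)):
        q = by_well.get(wk)
        if q is None:
            q = by_group.get(gk)
        if q is None:
            unmatched.append(wk)
            q = np.nan
        quantities[i] = q
    if unmatched:
        wells = sorted(set(unmatched))[:10]
        raise CoverageError(f"no normalization entry for well(s): {wells}")

    factor = quantities / scale
    for col in ("ocr", "ecar", "per"):
        df[col] = df[col] / factor
    norm_unit = "per 1e3 cells" if unit == "cells" else "per µg protein"
    report = table.report.merge(ReadReport(messages=[f"normalized {norm_unit}"]))
    return RateTable(df, normalized=True, norm_unit=norm_unit, report=report)
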