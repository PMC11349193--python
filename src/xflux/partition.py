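"""Map measurement indices to energetic states and extract state-level rates.

The three-injection stress tests tie measurement windows to energetic
states.  Mito Stress Test (oligomycin, FCCP, rotenone/antimycin A):
``basal``, ``uncoupled``, ``maxresp``, ``nonmito``.  Glyco Stress Test
(glucose, monensin, 2-DG): ``no_glucose``, ``glucose``, ``max_glyc``,
``twodg``.  The default 12-measurement protocol splits into four equal
windows of three; windows are fully configurable per state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from ._util import read_text_or_str
from .errors import LayoutError, MissingAssayError, ValidationError
from .wave_io import RateTable

MITO_STATES = ("basal", "uncoupled", "maxresp", "nonmito")
GLYCO_STATES = ("no_glucose", "glucose", "max_glyc", "twodg")
CANONICAL_STATES = {"MITO": MITO_STATES, "GLYCO": GLYCO_STATES}

_AGGREGATORS = ("mean", "max", "last")


@dataclass(frozen=True)
class StateWindow:
    """One energetic state: its assay, measurement indices and aggregator."""

    assay: str
    measurements: frozenset[int]
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValidationError("state window needs a non-empty measurement set")
        if any(m < 1 for m in self.measurements):
            raise ValidationError("measurement indices are 1-based positive integers")
        if self.aggregator not in _AGGREGATORS:
            raise ValidationError(f"aggregator must be one of {_AGGREGATORS}")


@dataclass
class PartitionScheme:
    """Mapping from state names to :class:`StateWindow`."""

    states: dict[str, StateWindow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # canonical states of one assay must not share measurements
        for assay, names in CANONICAL_STATES.items():
            used: dict[int, str] = {}
            for name in names:
                win = self.states.get(name)
                if win is None or win.assay != assay:
                    continue
                for m in win.measurements:
                    if m in used:
                        raise ValidationError(
                            f"states {used[m]!r} and {name!r} overlap at measurement {m}"
                        )
                    used[m] = name

    @property
    def assays(self) -> set[str]:
        return {w.assay for w in self.states.values()}

    def for_assay(self, assays: Iterable[str]) -> "PartitionScheme":
        """Restrict the scheme to states whose assay is in ``assays``."""
        keep = set(assays)
        return PartitionScheme(
            {n: w for n, w in self.states.items() if w.assay in keep}
        )

    def has_energetics_states(self, assay: str) -> bool:
        names = CANONICAL_STATES.get(assay, ())
        return all(n in self.states for n in names)

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            name: {
                "assay": w.assay,
                "measurements": sorted(w.measurements),
                "aggregator": w.aggregator,
            }
            for name, w in self.states.items()
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PartitionScheme":
        text = read_text_or_str(source)
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ValidationError("partition scheme YAML must map state -> window")
        states = {}
        for name, spec in doc.items():
            states[name] = StateWindow(
                assay=str(spec["assay"]).upper(),
                measurements=frozenset(int(m) for m in spec["measurements"]),
                aggregator=spec.get("aggregator", "mean"),
            )
        return cls(states)


def default_scheme(n_measurements: int = 12) -> PartitionScheme:
    """Equal four-way split of the measurement axis for both stress tests.

    Windows of width ``n/4`` in injection order; aggregator ``mean`` except
    ``max`` for the FCCP (``maxresp``) and monensin (``max_glyc``) phases,
    whose maximal rates are transient.
    """
    if n_measurements % 4 != 0 or n_measurements < 4:
        raise LayoutError(
            f"n_measurements={n_measurements} is not divisible by 4; "
            "supply an explicit PartitionScheme for non-standard layouts"
        )
    w = n_measurements // 4
    windows = [frozenset(range(i * w + 1, (i + 1) * w + 1)) for i in range(4)]
    states: dict[str, StateWindow] = {}
    for assay, names in CANONICAL_STATES.items():
        for name, win in zip(names, windows):
            agg = "max" if name in ("maxresp", "max_glyc") else "mean"
            states[name] = StateWindow(assay, win, agg)
    return PartitionScheme(states)


@dataclass
class PartitionReport:
    """Outcome of :func:`validate_scheme` — report-only, never raises."""

    overlaps: list[str] = field(default_factory=list)
    out_of_range: list[str] = field(default_factory=list)
    unused_assays: list[str] = field(default_factory=list)
    missing_for_energetics: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.overlaps or self.out_of_range or self.missing_for_energetics)


def validate_scheme(scheme: PartitionScheme, table: RateTable) -> PartitionReport:
    """Check a scheme against a table: overlaps, range, energetics coverage."""
    report = PartitionReport()
    for assay, names in CANONICAL_STATES.items():
        used: dict[int, str] = {}
        for name in names:
            win = scheme.states.get(name)
            if win is None or win.assay != assay:
                continue
            for m in win.measurements:
                if m in used:
                    report.overlaps.append(f"{used[m]}/{name} overlap at measurement {m}")
                used[m] = name

    present = set(table.assay_types)
    for assay in sorted(scheme.assays - present):
        report.unused_assays.append(f"{assay} states unused (no {assay} wells in data)")

    for name, win in scheme.states.items():
        if win.assay not in present:
            continue
        avail = set(
            table.data.loc[table.data["assay_type"] == win.assay, "measurement"].unique()
        )
        out = sorted(set(win.measurements) - avail)
        if out:
            report.out_of_range.append(f"{name}: measurements {out} absent from data")

    for assay in present & set(CANONICAL_STATES):
        for name in CANONICAL_STATES[assay]:
            if name not in scheme.states:
                report.missing_for_energetics.append(f"{name} ({assay})")
    return report


def _aggregate(values: pd.Series, measurements: pd.Series, how: str) -> tuple[float, int]:
    finite = values.notna()
    used = values[finite]
    if len(used) == 0:
        return float("nan"), 0
    if how == "mean":
        out = float(used.mean())
    elif how == "max":
        out = float(used.max())
    else:  # last: value at the largest measurement index with a finite value
        out = float(used.loc[measurements[finite].idxmax()])
    return out, int(len(used))


def partition_data(table: RateTable, scheme: PartitionScheme) -> pd.DataFrame:
    """Reduce each well's rates to one row per energetic state.

    Returns a DataFrame with columns ``plate_id, exp_group, well, assay_type,
    state, ocr_state, ecar_state, n_points``.  Aggregation skips
    flagged-missing points and records the number of points actually used.
    States whose measurement indices are entirely absent from the data are
    dropped with a warning.
    """
    present = set(table.assay_types)
    absent = sorted(scheme.assays - present)
    if absent:
        raise MissingAssayError(
            f"scheme references assay type(s) {absent} not in data "
            f"(available: {sorted(present)})"
        )

    rows: list[dict] = []
    by_assay = dict(tuple(table.data.groupby("assay_type")))
    for name, win in scheme.states.items():
        sub = by_assay[win.assay]
        avail = set(sub["measurement"].unique())
        missing = sorted(set(win.measurements) - avail)
        if missing:
            warnings.warn(
                f"state {name!r}: measurement(s) {missing} absent from "
                f"{win.assay} data; state omitted",
                stacklevel=2,
            )
            continue
        in_win = sub[sub["measurement"].isin(win.measurements)]
        for (plate, group, well), g in in_win.groupby(
            ["plate_id", "exp_group", "well"], sort=True
        ):
            ocr, n_ocr = _aggregate(g["ocr"], g["measurement"], win.aggregator)
            ecar, n_ecar = _aggregate(g["ecar"], g["measurement"], win.aggregator)
            rows.append(
                {
                    "plate_id": plate,
                    "exp_group": group,
                    "well": well,
                    "assay_type": win.assay,
                    "state": name,
                    "ocr_state": ocr,
                    "ecar_state": ecar,
                    "n_points": max(n_ocr, n_ecar),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "exp_group",
            "well",
            "assay_type",
            "state",
            "ocr_state",
            "ecar_state",
            "n_points",
        ],
    )
    return out.sort_values(
        ["plate_id", "exp_group", "well", "state"], kind="stable"
    ).reset_index(drop=True)
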