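"""Synthetic Seahorse plates with known ground truth.

The generator emulates the Wave rate-export dialect for a standard
12-measurement, three-injection stress test: per well and measurement the
rate is the phase mean of the enclosing window, plus an additive per-plate
effect (common to all wells of a plate — the minimal structure that makes
inter-plate variation identifiable by a random-intercept model) and
independent well-measurement noise.  Kinetics are piecewise constant so the
ground-truth energetics stay analytic; Group labels follow the
``"name ASSAY"`` convention and background wells emit near-zero rates.

Measurement cadence is 6.5 min (the typical mix/wait/measure cycle).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import read_text_or_str
from .energetics import (
    AssayConfig,
    ENERGETICS_QUANTITIES,
    atp_glyc,
    atp_ox,
    ocr_components,
    ppr_glyc,
    ppr_resp,
    ppr_total,
)
from .errors import MissingStateError, ValidationError
from .partition import CANONICAL_STATES, default_scheme
from .wave_io import RATE_COLUMNS, RateTable

MEASUREMENT_CADENCE_MIN = 6.5


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group in one assay: per-state mean (OCR, ECAR)."""

    name: str
    assay_type: str  # MITO | GLYCO
    phase_means: dict[str, tuple[float, float]]  # state -> (ocr, ecar)
    well_count: int = 6

    def __post_init__(self) -> None:
        canonical = CANONICAL_STATES.get(self.assay_type)
        if canonical is None:
            raise ValidationError(f"unknown assay_type {self.assay_type!r}")
        missing = [s for s in canonical if s not in self.phase_means]
        if missing:
            raise ValidationError(
                f"group {self.name!r} ({self.assay_type}) lacks phase means for {missing}"
            )
        if self.well_count < 1:
            raise ValidationError("well_count must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Full synthetic-experiment description; fixed seed => identical output."""

    groups: tuple[GroupSpec, ...]
    n_measurements: int = 12
    noise_sd_well: float = 0.0
    noise_sd_plate: float = 0.0
    n_plates: int = 1
    seed: int = 0
    background_wells: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd_well < 0 or self.noise_sd_plate < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.n_measurements < 4:
            raise ValidationError("n_measurements must be >= 4")
        if self.n_plates < 1:
            raise ValidationError("n_plates must be >= 1")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "FixtureSpec":
        text = read_text_or_str(source)
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "groups" not in doc:
            raise ValidationError("fixture spec YAML must contain a 'groups' list")
        groups = []
        for g in doc["groups"]:
            try:
                groups.append(
                    GroupSpec(
                        name=g["name"],
                        assay_type=str(g["assay_type"]).upper(),
                        phase_means={
                            s: (float(v[0]), float(v[1]))
                            for s, v in g["phase_means"].items()
                        },
                        well_count=int(g.get("well_count", 6)),
                    )
                )
            except KeyError as e:
                raise ValidationError(f"fixture group missing field {e}") from e
        scalar = {
            k: doc[k]
            for k in (
                "n_measurements",
                "noise_sd_well",
                "noise_sd_plate",
                "n_plates",
                "seed",
                "background_wells",
            )
            if k in doc
        }
        return cls(groups=tuple(groups), **scalar)


def default_fixture_spec(
    *,
    n_plates: int = 1,
    noise_sd_well: float = 0.0,
    noise_sd_plate: float = 0.0,
    seed: int = 0,
    well_count: int = 6,
) -> FixtureSpec:
    """Two experimental groups, each assayed by Mito and Glyco Stress Tests.

    Phase means are typical adherent-cell XF96 magnitudes (OCR pmol O2/min,
    ECAR mpH/min at ~3e4 cells/well): Group_1 is OXPHOS-leaning, Group_2
    glycolysis-leaning with a compressed respiratory reserve.
    """
    groups = (
        GroupSpec(
            "Group_1",
            "MITO",
            {
                "basal": (120.0, 30.0),
                "uncoupled": (50.0, 40.0),
                "maxresp": (200.0, 35.0),
                "nonmito": (20.0, 15.0),
            },
            well_count,
        ),
        GroupSpec(
            "Group_1",
            "GLYCO",
            {
                "no_glucose": (80.0, 12.0),
                "glucose": (100.0, 45.0),
                "max_glyc": (90.0, 90.0),
                "twodg": (70.0, 15.0),
            },
            well_count,
        ),
        GroupSpec(
            "Group_2",
            "MITO",
            {
                "basal": (80.0, 55.0),
                "uncoupled": (40.0, 70.0),
                "maxresp": (110.0, 60.0),
                "nonmito": (15.0, 20.0),
            },
            well_count,
        ),
        GroupSpec(
            "Group_2",
            "GLYCO",
            {
                "no_glucose": (50.0, 18.0),
                "glucose": (65.0, 75.0),
                "max_glyc": (60.0, 140.0),
                "twodg": (45.0, 20.0),
            },
            well_count,
        ),
    )
    return FixtureSpec(
        groups=groups,
        n_plates=n_plates,
        noise_sd_well=noise_sd_well,
        noise_sd_plate=noise_sd_plate,
        seed=seed,
    )


def _well_names(n: int) -> list[str]:
    """A01, A02, ... in 96-well (12-column) order."""
    return [f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}" for i in range(n)]


def _state_of_measurement(spec: FixtureSpec, assay: str) -> dict[int, str]:
    scheme = default_scheme(spec.n_measurements)
    out = {}
    for name in CANONICAL_STATES[assay]:
        for m in scheme.states[name].measurements:
            out[m] = name
    return out


def simulate_plate(spec: FixtureSpec, plate_index: int = 0) -> RateTable:
    """Simulate one plate of the experiment described by ``spec``.

    rate = phase mean + plate effect ~ N(0, noise_sd_plate²), one draw per
    plate per channel, + well-measurement noise ~ N(0, noise_sd_well²);
    time = 6.5 min × (measurement − 1).
    """
    rng = np.random.default_rng([spec.seed, plate_index])
    plate_ocr_shift = rng.normal(0.0, spec.noise_sd_plate) if spec.noise_sd_plate else 0.0
    plate_ecar_shift = rng.normal(0.0, spec.noise_sd_plate) if spec.noise_sd_plate else 0.0

    n_exp_wells = sum(g.well_count for g in spec.groups)
    wells = _well_names(n_exp_wells + spec.background_wells)
    rows: list[dict] = []
    w = 0
    plate_id = f"plate_{plate_index + 1:02d}"
    for g in spec.groups:
        state_of = _state_of_measurement(spec, g.assay_type)
        for _ in range(g.well_count):
            well = wells[w]
            w += 1
            for m in range(1, spec.n_measurements + 1):
                ocr_mu, ecar_mu = g.phase_means[state_of[m]]
                noise = (
                    rng.normal(0.0, spec.noise_sd_well, size=2)
                    if spec.noise_sd_well
                    else (0.0, 0.0)
                )
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well": well,
                        "group_label": f"{g.name} {g.assay_type}",
                        "exp_group": g.name,
                        "assay_type": g.assay_type,
                        "measurement": m,
                        "time_min": MEASUREMENT_CADENCE_MIN * (m - 1),
                        "ocr": ocr_mu + plate_ocr_shift + noise[0],
                        "ecar": ecar_mu + plate_ecar_shift + noise[1],
                        "per": np.nan,
                    }
                )
    # instrument blanks: near-zero rates, excluded on read
    for _ in range(spec.background_wells):
        well = wells[w]
        w += 1
        for m in range(1, spec.n_measurements + 1):
            bg = rng.normal(0.0, 0.5, size=2) if spec.noise_sd_well else (0.0, 0.0)
            rows.append(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "group_label": "Background",
                    "exp_group": "Background",
                    "assay_type": "",
                    "measurement": m,
                    "time_min": MEASUREMENT_CADENCE_MIN * (m - 1),
                    "ocr": bg[0],
                    "ecar": bg[1],
                    "per": np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=list(RATE_COLUMNS))
    return RateTable(df)


def simulate_experiment(spec: FixtureSpec) -> list[RateTable]:
    """One RateTable per plate, deterministic under the spec's seed."""
    return [simulate_plate(spec, i) for i in range(spec.n_plates)]


def write_wave_workbook(table: RateTable, path: str | Path) -> Path:
    """Write a RateTable in the Wave rate-export dialect.

    ``.xlsx`` produces a workbook with a single "Rate" sheet; ``.csv``
    writes the same columns as plain text.  Round-trips through
    ``read_rate_file`` preserve all numeric fields and labels.
    """
    path = Path(path)
    out = pd.DataFrame(
        {
            "Measurement": table.data["measurement"],
            "Well": table.data["well"],
            "Group": table.data["group_label"],
            "Time": table.data["time_min"],
            "OCR": table.data["ocr"],
            "ECAR": table.data["ecar"],
            "PER": table.data["per"],
        }
    )
    try:
        if path.suffix.lower() == ".csv":
            out.to_csv(path, index=False)
        else:
            # xlsx float cells are serialized at 16 significant digits, one
            # short of round-trip; write exact decimal representations
            # instead (the reader parses number-like text transparently)
            exact = out.copy()
            for col in ("Time", "OCR", "ECAR", "PER"):
                exact[col] = [
                    None if pd.isna(v) else repr(float(v)) for v in exact[col]
                ]
            with pd.ExcelWriter(path, engine="openpyxl") as xl:
                exact.to_excel(xl, sheet_name="Rate", index=False)
    except OSError as e:
        raise OSError(f"cannot write workbook {path}: {e}") from e
    return path


def write_experiment(spec: FixtureSpec, out_dir: str | Path, fmt: str = "xlsx") -> list[Path]:
    """Simulate and write every plate of ``spec`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, table in enumerate(simulate_experiment(spec)):
        paths.append(write_wave_workbook(table, out_dir / f"plate_{i + 1:02d}.{fmt}"))
    return paths


def ground_truth_energetics(spec: FixtureSpec, cfg: AssayConfig) -> pd.DataFrame:
    """Noise-free expected JATP per experimental group.

    Applies the energetics closed forms directly to the phase means — an
    independent oracle path that bypasses parsing and partitioning.  The
    respiratory correction's non-mitochondrial OCR estimate mirrors the
    pipeline default: the group's MITO-assay nonmito phase mean when that
    group is present, else 0.
    """
    mito = {g.name: g for g in spec.groups if g.assay_type == "MITO"}
    glyco = {g.name: g for g in spec.groups if g.assay_type == "GLYCO"}

    rows = []
    for name in sorted(set(mito) | set(glyco)):
        row: dict = {"exp_group": name, **{q: np.nan for q in ENERGETICS_QUANTITIES}}
        if name in mito:
            pm = mito[name].phase_means
            comp = ocr_components(
                pm["basal"][0],
                pm["uncoupled"][0],
                pm["maxresp"][0],
                pm["nonmito"][0],
                max_coupled_mode=cfg.max_coupled_mode,
            )
            row["atp_basal_ox"] = atp_ox(comp.coupled_basal, comp.mito_basal, cfg)
            row["atp_max_ox"] = atp_ox(comp.coupled_max, comp.mito_max, cfg)
        if name in glyco:
            pm = glyco[name].phase_means
            if cfg.glyc_ocr_correction == "group" and name in mito:
                nonmito_est = mito[name].phase_means["nonmito"][0]
            else:
                nonmito_est = 0.0
            baseline = pm["no_glucose"][1] if cfg.subtract_nonglycolytic else 0.0
            for kind, state in (("basal", "glucose"), ("max", "max_glyc")):
                ecar = pm[state][1] - baseline
                ocr_mito = pm[state][0] - nonmito_est
                glyc = ppr_glyc(ppr_total(ecar, cfg), ppr_resp(ocr_mito, cfg))
                row[f"atp_{kind}_glyc"] = atp_glyc(glyc, ocr_mito, cfg)
        if name in mito or name in glyco:
            rows.append(row)
    if not rows:
        raise MissingStateError("fixture spec has no MITO or GLYCO groups")
    return pd.DataFrame(rows, columns=["exp_group", *ENERGETICS_QUANTITIES])
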