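"""Convert state-level OCR/ECAR into ATP production rates (JATP).

The conversion follows the Mookerjee accounting of oxidative and glycolytic
ATP production.  Oxidative side: ATP-linked (coupled) OCR and mitochondrial
OCR, each doubled to convert O2 to O atoms, are weighted by P/O ratios for
oxidative phosphorylation and TCA-cycle substrate-level phosphorylation.
Glycolytic side: ECAR is converted to a total proton efflux rate via the
medium buffering factor; the respiratory contribution — CO2 from oxidized
substrate hydrating to bicarbonate plus a proton, with the ionized fraction
set by the medium pH and carbonic-acid pK1 — is subtracted; the remaining
(glycolytic) proton rate maps 1:1 onto lactate export, plus a term for
glycolytic ATP tied to pyruvate that is oxidized in mitochondria.

With the default buffering-factor units (mpH/pmol H+), JATP is in
pmol ATP/min.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import read_text_or_str
from .errors import ValidationError
from .partition import MITO_STATES


@dataclass(frozen=True)
class AssayConfig:
    """Biochemical constants of the assay medium and substrate.

    Defaults are the XF DMEM / glucose-oxidation values: pH 7.4, carbonic
    acid pK1 6.093 at 37°C, buffering factor 0.1 mpH per pmol H+, maximum
    H+/O2 of CO2 hydration 1.0, P/O 2.486 (oxidative phosphorylation),
    0.121 (TCA substrate-level), 0.167 (glycolysis-linked oxidation), and
    1 ATP per lactate exported.  Every constant is overridable for other
    media or substrates.
    """

    ph: float = 7.4
    pk1: float = 6.093
    buffer_factor: float = 0.1  # mpH per pmol H+
    max_h_per_o2: float = 1.0
    po_oxphos: float = 2.486
    po_tca: float = 0.121
    po_glyc: float = 0.167
    atp_per_lactate: float = 1.0
    # maximal coupled OCR = maxresp - uncoupled (proton leak assumed constant)
    # or maxresp - nonmito when max_coupled_mode == "nonmito"
    max_coupled_mode: str = "uncoupled"
    # subtract the pre-glucose ECAR from basal/max glycolytic ECAR
    subtract_nonglycolytic: bool = False
    # respiratory correction of glycolytic JATP: nonmito OCR borrowed from the
    # MITO assay at group level ("group"), or disabled ("none")
    glyc_ocr_correction: str = "group"

    def __post_init__(self) -> None:
        if self.buffer_factor <= 0:
            raise ValidationError("buffer_factor must be > 0")
        if not (np.isfinite(self.ph) and np.isfinite(self.pk1)):
            raise ValidationError("ph and pk1 must be finite")
        for name in ("max_h_per_o2", "po_oxphos", "po_tca", "po_glyc", "atp_per_lactate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.max_coupled_mode not in ("uncoupled", "nonmito"):
            raise ValidationError("max_coupled_mode must be 'uncoupled' or 'nonmito'")
        if self.glyc_ocr_correction not in ("group", "none"):
            raise ValidationError("glyc_ocr_correction must be 'group' or 'none'")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AssayConfig":
        text = read_text_or_str(source)
        doc = yaml.safe_load(text) or {}
        return cls(**doc)


@dataclass(frozen=True)
class OcrComponents:
    """ATP-linked and mitochondrial OCR components, pmol O2/min."""

    mito_basal: float
    coupled_basal: float
    mito_max: float
    coupled_max: float

    @property
    def negative(self) -> list[str]:
        return [k for k, v in asdict(self).items() if v < 0]


def respiratory_fraction(ph: float, pk1: float) -> float:
    """Fraction of CO2-derived acid ionized at assay pH.

    ``10^(pH − pK1) / (1 + 10^(pH − pK1))`` — the Henderson–Hasselbalch
    ionized fraction; 0.5 when pH == pK1, increasing in pH.
    """
    r = 10.0 ** (ph - pk1)
    return r / (1.0 + r)


def ppr_total(ecar: float, cfg: AssayConfig) -> float:
    """Total proton efflux rate (pmol H+/min) from ECAR (mpH/min)."""
    return ecar / cfg.buffer_factor


def ppr_resp(ocr_mito: float, cfg: AssayConfig) -> float:
    """Respiratory (CO2-derived) proton efflux rate for a mitochondrial OCR."""
    return ocr_mito * cfg.max_h_per_o2 * respiratory_fraction(cfg.ph, cfg.pk1)


def ppr_glyc(ppr_tot: float, ppr_resp_: float) -> float:
    """Glycolytic proton efflux: total minus respiratory.  May be negative
    (over-correction); callers flag but do not clip."""
    return ppr_tot - ppr_resp_


def atp_glyc(ppr_glyc_: float, ocr_mito: float, cfg: AssayConfig) -> float:
    """Glycolytic JATP: lactate-linked protons plus glycolytic ATP made while
    feeding pyruvate into mitochondrial oxidation."""
    return ppr_glyc_ * cfg.atp_per_lactate + ocr_mito * 2.0 * cfg.po_glyc


def atp_ox(coupled: float, mito: float, cfg: AssayConfig) -> float:
    """Oxidative JATP from coupled and mitochondrial OCR components.

    O2 is diatomic, hence the factor 2 converting O2 to O atoms before the
    P/O weights.
    """
    return coupled * 2.0 * cfg.po_oxphos + mito * 2.0 * cfg.po_tca


def ocr_components(
    basal: float,
    uncoupled: float,
    maxresp: float,
    nonmito: float,
    *,
    max_coupled_mode: str = "uncoupled",
) -> OcrComponents:
    """Derive ATP-linked and mitochondrial OCR from the four state OCRs."""
    coupled_max_ref = uncoupled if max_coupled_mode == "uncoupled" else nonmito
    return OcrComponents(
        mito_basal=basal - nonmito,
        coupled_basal=basal - uncoupled,
        mito_max=maxresp - nonmito,
        coupled_max=maxresp - coupled_max_ref,
    )


ENERGETICS_QUANTITIES = ("atp_basal_ox", "atp_max_ox", "atp_basal_glyc", "atp_max_glyc")

_ENERGETICS_COLUMNS = (
    "plate_id",
    "exp_group",
    "well",
    "assay_type",
) + ENERGETICS_QUANTITIES


@dataclass
class QualityReport:
    """Per-well flags raised during energetics: negative components,
    missing states, absent respiratory-correction estimates."""

    flags: list[dict] = field(default_factory=list)

    def add(self, plate: str, well: str, kind: str, detail: str) -> None:
        self.flags.append(
            {"plate_id": plate, "well": well, "kind": kind, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, columns=["plate_id", "well", "kind", "detail"])


@dataclass
class EnergeticsResult:
    """Per-well basal/maximal JATP records plus the quality report.

    ``data`` has one row per well: MITO wells carry the oxidative columns,
    GLYCO wells the glycolytic ones; the other pathway's columns are NaN.
    All JATP values are pmol ATP/min under default buffering-factor units.
    """

    data: pd.DataFrame
    quality: QualityReport = field(default_factory=QualityReport)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.data.copy()
        out["unit"] = "pmol ATP/min"
        out.to_csv(path, index=False)
        return path


def _state_lookup(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {r.state: r for r in df.itertuples()}


def get_energetics(partitioned: pd.DataFrame, cfg: AssayConfig) -> EnergeticsResult:
    """Compute per-well basal and maximal JATP from partitioned rates.

    Oxidative outputs need the four Mito Stress Test states per well.
    Glycolytic outputs use GLYCO-assay wells: basal ECAR from the glucose
    state, maximal from the monensin state (each optionally minus the
    pre-glucose state), with the respiratory correction's mitochondrial OCR
    taken as that GLYCO well's OCR at the same state minus the group-mean
    non-mitochondrial OCR from the MITO assay on the same plate (the Glyco
    Stress Test has no rotenone/antimycin phase of its own; 0 when no MITO
    data exists).
    """
    quality = QualityReport()
    rows: list[dict] = []

    # group-level nonmito OCR estimates from the MITO assay, per plate x group
    mito = partitioned[partitioned["assay_type"] == "MITO"]
    nonmito_by_group: dict[tuple[str, str], float] = {}
    nm = mito[mito["state"] == "nonmito"]
    if len(nm):
        nonmito_by_group = (
            nm.groupby(["plate_id", "exp_group"])["ocr_state"].mean().to_dict()
        )

    for (plate, group, well), g in partitioned.groupby(
        ["plate_id", "exp_group", "well"], sort=True
    ):
        assay = g["assay_type"].iloc[0]
        states = _state_lookup(g)
        row: dict = {
            "plate_id": plate,
            "exp_group": group,
            "well": well,
            "assay_type": assay,
            **{q: np.nan for q in ENERGETICS_QUANTITIES},
        }
        if assay == "MITO":
            missing = [s for s in MITO_STATES if s not in states]
            if missing:
                quality.add(plate, well, "missing_state", f"MITO states absent: {missing}")
            else:
                comp = ocr_components(
                    states["basal"].ocr_state,
                    states["uncoupled"].ocr_state,
                    states["maxresp"].ocr_state,
                    states["nonmito"].ocr_state,
                    max_coupled_mode=cfg.max_coupled_mode,
                )
                if comp.negative:
                    quality.add(
                        plate, well, "negative_component",
                        f"negative OCR component(s): {comp.negative}",
                    )
                row["atp_basal_ox"] = atp_ox(comp.coupled_basal, comp.mito_basal, cfg)
                row["atp_max_ox"] = atp_ox(comp.coupled_max, comp.mito_max, cfg)
        elif assay == "GLYCO":
            needed = ("glucose", "max_glyc") + (
                ("no_glucose",) if cfg.subtract_nonglycolytic else ()
            )
            missing = [s for s in needed if s not in states]
            if missing:
                quality.add(plate, well, "missing_state", f"GLYCO states absent: {missing}")
            else:
                if cfg.glyc_ocr_correction == "group":
                    nonmito_est = nonmito_by_group.get((plate, group))
                    if nonmito_est is None:
                        nonmito_est = 0.0
                        quality.add(
                            plate, well, "no_nonmito_estimate",
                            "no MITO nonmito OCR for this plate/group; correction uses 0",
                        )
                else:
                    nonmito_est = 0.0
                baseline = (
                    states["no_glucose"].ecar_state if cfg.subtract_nonglycolytic else 0.0
                )
                for kind, state in (("basal", "glucose"), ("max", "max_glyc")):
                    ecar = states[state].ecar_state - baseline
                    ocr_mito = states[state].ocr_state - nonmito_est
                    tot = ppr_total(ecar, cfg)
                    resp = ppr_resp(ocr_mito, cfg)
                    glyc = ppr_glyc(tot, resp)
                    if glyc < 0:
                        quality.add(
                            plate, well, "negative_ppr_glyc",
                            f"{kind}: respiratory correction exceeds total proton rate",
                        )
                    row[f"atp_{kind}_glyc"] = atp_glyc(glyc, ocr_mito, cfg)
        rows.append(row)

    data = pd.DataFrame(rows, columns=list(_ENERGETICS_COLUMNS))
    return EnergeticsResult(data, quality)
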