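"""Rate, bioenergetic-scope and ATP plots.

Every plot function returns a :class:`PlotBundle`: the matplotlib figure,
the exact tidy table that was plotted, and the metadata needed to re-render
it.  Plots never recompute statistics — the summaries come from
``replicate_stats`` and the bundle's data table is the single source of
truth, so custom downstream visualization starts from the table, not the
figure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no display required

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .energetics import ENERGETICS_QUANTITIES
from .errors import ValidationError
from .partition import PartitionScheme
from .replicate_stats import rate_summary
from .wave_io import RateTable

_RATE_UNITS = {"ocr": "OCR (pmol O2/min)", "ecar": "ECAR (mpH/min)"}
_JATP_UNIT = "JATP (pmol ATP/min)"


@dataclass
class PlotBundle:
    """A rendered figure plus the tidy table it was rendered from."""

    figure: plt.Figure
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def save(self, basepath: str | Path, formats: tuple[str, ...] = ("png", "svg")) -> list[Path]:
        """Save the figure as PNG/SVG and the plot data as CSV alongside."""
        basepath = Path(basepath)
        basepath.parent.mkdir(parents=True, exist_ok=True)
        written = []
        for fmt in formats:
            p = basepath.with_suffix(f".{fmt}")
            self.figure.savefig(p, dpi=150)
            written.append(p)
        csv = basepath.with_suffix(".csv")
        self.data.to_csv(csv, index=False)
        written.append(csv)
        return written

    def close(self) -> None:
        plt.close(self.figure)


def _unit_suffix(table: RateTable) -> str:
    return f", {table.norm_unit}" if table.normalized and table.norm_unit else ""


def rate_plot(
    table: RateTable,
    measure: str = "ocr",
    variance: str = "sd",
    level: float = 0.95,
    scheme: PartitionScheme | None = None,
) -> PlotBundle:
    """Mean group OCR or ECAR over measurement time with a variance band.

    One line per experimental group (x = mean group time in minutes), one
    panel per assay type; the shaded band is mean ± SD or the CI.  When a
    partition scheme is given, vertical markers are drawn at its window
    boundaries (the injection points).
    """
    if measure not in ("ocr", "ecar"):
        raise ValidationError(f"unknown measure {measure!r}; use 'ocr' or 'ecar'")
    summary = rate_summary(table, variance=variance, level=level)
    data = summary[summary["measure"] == measure].reset_index(drop=True)

    assays = sorted(data["assay_type"].unique())
    fig, axes = plt.subplots(
        1, max(len(assays), 1), figsize=(5.5 * max(len(assays), 1), 4), squeeze=False
    )
    for ax, assay in zip(axes[0], assays):
        sub = data[data["assay_type"] == assay]
        for group, g in sub.groupby("exp_group", sort=True):
            g = g.sort_values("measurement")
            ax.plot(g["time_min"], g["mean"], marker="o", ms=3, label=group)
            if g[["band_low", "band_high"]].notna().all(axis=None):
                ax.fill_between(g["time_min"], g["band_low"], g["band_high"], alpha=0.25)
        if scheme is not None:
            bounds = _injection_times(scheme, assay, sub)
            for t in bounds:
                ax.axvline(t, color="grey", ls=":", lw=0.8)
        ax.set_title(assay)
        ax.set_xlabel("Time (min)")
        ax.set_ylabel(_RATE_UNITS[measure] + _unit_suffix(table))
        ax.legend(fontsize=8)
    fig.tight_layout()
    meta = {
        "variance": variance,
        "level": level,
        "measure": measure,
        "norm_unit": table.norm_unit,
    }
    return PlotBundle(fig, data, meta)


def _injection_times(
    scheme: PartitionScheme, assay: str, summary: pd.DataFrame
) -> list[float]:
    """Mid-gap times between consecutive state windows of one assay."""
    wins = sorted(
        (min(w.measurements), max(w.measurements))
        for w in scheme.states.values()
        if w.assay == assay
    )
    t_of = dict(zip(summary["measurement"], summary["time_min"]))
    times = []
    for (_, end), (start, _) in zip(wins, wins[1:]):
        if end in t_of and start in t_of:
            times.append((t_of[end] + t_of[start]) / 2.0)
    return times


def _require_quantities(summaries: pd.DataFrame, group: str) -> pd.DataFrame | None:
    g = summaries[summaries["exp_group"] == group]
    have = set(g["quantity"])
    missing = [q for q in ENERGETICS_QUANTITIES if q not in have]
    if missing:
        warnings.warn(f"group {group!r} lacks {missing}; skipped", stacklevel=3)
        return None
    return g.set_index("quantity")


def _err(row: pd.Series, variance: str) -> tuple[float, float]:
    """(minus, plus) error-bar extents for one summary row."""
    if variance == "sd":
        sd = row["sd"]
        return (sd, sd) if np.isfinite(sd) else (0.0, 0.0)
    lo, hi = row["ci_low"], row["ci_high"]
    if np.isfinite(lo) and np.isfinite(hi):
        return (row["mean"] - lo, hi - row["mean"])
    return (0.0, 0.0)


def bioscope_plot(summaries: pd.DataFrame, variance: str = "sd") -> PlotBundle:
    """Bioenergetic scope: glycolytic JATP (x) vs oxidative JATP (y).

    Two points per group — basal (circle) and maximal (triangle) — sharing a
    color; horizontal/vertical bars are the glycolytic/oxidative SD or CI.
    """
    if variance not in ("sd", "ci"):
        raise ValidationError("variance must be 'sd' or 'ci'")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    rows = []
    markers = {"basal": "o", "max": "^"}
    for i, group in enumerate(sorted(summaries["exp_group"].unique())):
        g = _require_quantities(summaries, group)
        if g is None:
            continue
        color = f"C{i % 10}"
        for cond in ("basal", "max"):
            gx = g.loc[f"atp_{cond}_glyc"]
            gy = g.loc[f"atp_{cond}_ox"]
            xm, xp = _err(gx, variance)
            ym, yp = _err(gy, variance)
            ax.errorbar(
                gx["mean"], gy["mean"],
                xerr=[[xm], [xp]], yerr=[[ym], [yp]],
                fmt=markers[cond], color=color, capsize=3,
                label=f"{group} ({cond})",
            )
            rows.append(
                {
                    "exp_group": group,
                    "condition": cond,
                    "glyc_mean": gx["mean"],
                    "glyc_err_low": gx["mean"] - xm,
                    "glyc_err_high": gx["mean"] + xp,
                    "ox_mean": gy["mean"],
                    "ox_err_low": gy["mean"] - ym,
                    "ox_err_high": gy["mean"] + yp,
                }
            )
    ax.set_xlabel(f"Glycolysis {_JATP_UNIT}")
    ax.set_ylabel(f"OXPHOS {_JATP_UNIT}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return PlotBundle(fig, pd.DataFrame(rows), {"variance": variance})


def atp_plot(summaries: pd.DataFrame, variance: str = "sd") -> PlotBundle:
    """Grouped crossbar chart of JATP by condition × pathway × group.

    x positions are basal/max × OXPHOS/glycolysis; the center line is the
    group mean and the crossbar spans mean ± SD or the CI.  Crossbars are
    suppressed (centers still drawn) where the spread is undefined (n = 1).
    """
    if variance not in ("sd", "ci"):
        raise ValidationError("variance must be 'sd' or 'ci'")
    order = list(ENERGETICS_QUANTITIES)
    labels = {
        "atp_basal_ox": "basal\nOXPHOS",
        "atp_max_ox": "max\nOXPHOS",
        "atp_basal_glyc": "basal\nglycolysis",
        "atp_max_glyc": "max\nglycolysis",
    }
    groups = sorted(summaries["exp_group"].unique())
    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = 0.8 / max(len(groups), 1)
    rows = []
    n_suppressed = 0
    for i, group in enumerate(groups):
        g = summaries[summaries["exp_group"] == group].set_index("quantity")
        color = f"C{i % 10}"
        for j, q in enumerate(order):
            if q not in g.index:
                continue
            r = g.loc[q]
            x = j + (i - (len(groups) - 1) / 2) * width
            lo_d, hi_d = _err(r, variance)
            has_bar = np.isfinite(r["sd" if variance == "sd" else "ci_low"])
            ax.hlines(r["mean"], x - width * 0.45, x + width * 0.45, color=color, lw=2)
            if has_bar:
                ax.add_patch(
                    plt.Rectangle(
                        (x - width * 0.45, r["mean"] - lo_d),
                        width * 0.9, lo_d + hi_d,
                        fill=False, edgecolor=color, lw=1,
                    )
                )
            else:
                n_suppressed += 1
            rows.append(
                {
                    "exp_group": group,
                    "quantity": q,
                    "mean": r["mean"],
                    "bar_low": r["mean"] - lo_d if has_bar else np.nan,
                    "bar_high": r["mean"] + hi_d if has_bar else np.nan,
                }
            )
    if n_suppressed:
        warnings.warn(
            f"{n_suppressed} crossbar(s) suppressed (single-well summaries)",
            stacklevel=2,
        )
    ax.set_xticks(range(len(order)), [labels[q] for q in order])
    ax.set_ylabel(_JATP_UNIT)
    handles = [plt.Line2D([], [], color=f"C{i % 10}", lw=2) for i in range(len(groups))]
    ax.legend(handles, groups, fontsize=8)
    fig.tight_layout()
    return PlotBundle(fig, pd.DataFrame(rows), {"variance": variance})
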