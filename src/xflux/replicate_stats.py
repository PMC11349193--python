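"""Replicate summarization: mean, SD and CI across technical and biological
replicates.

Within one plate, wells are technical replicates and an intercept-only
ordinary-least-squares summary (closed-form mean and t-based CI) applies.
Across plates, inter-plate variation is substantial, so the default is a
random-intercept linear mixed model fit by restricted maximum likelihood
(statsmodels ``MixedLM``): the group mean is the fixed intercept, its CI a
Wald-t interval with ``n_plates − 1`` denominator degrees of freedom, and
the reported SD is the total SD ``sqrt(between-plate variance + residual
variance)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import ENERGETICS_QUANTITIES, EnergeticsResult
from .errors import EmptyGroupError, ValidationError
from .wave_io import RateTable

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """One group × quantity summary row."""

    exp_group: str
    quantity: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_wells: int
    n_plates: int
    level: float
    method: str  # ols_intra | ols_inter | lmm_inter


def _check_level(level: float) -> None:
    if not 0 < level < 1:
        raise ValidationError(f"CI level must be in (0,1), got {level}")


def summarize_ols(values: Sequence[float], level: float = 0.95) -> dict:
    """Closed-form intercept-only OLS summary of i.i.d. replicate values.

    mean = sample mean; sd = sample SD (n−1 denominator);
    CI = mean ± t_{n−1, (1+level)/2} · sd/√n.  With a single value, sd and
    the CI are NaN (explicit missing markers).
    """
    _check_level(level)
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise EmptyGroupError("no finite values to summarize")
    mean = float(x.mean())
    if n == 1:
        return {"mean": mean, "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 1}
    sd = float(x.std(ddof=1))
    tcrit = float(stats.t.ppf((1 + level) / 2, df=n - 1))
    half = tcrit * sd / np.sqrt(n)
    return {
        "mean": mean,
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n": n,
    }


def summarize_lmm(
    values: pd.DataFrame | Iterable[tuple[str, float]],
    level: float = 0.95,
) -> dict:
    """Random-intercept mixed-model summary of (plate_id, value) pairs.

    Fit by REML.  mean = fixed intercept; CI = intercept ± t_{n_plates−1} · SE;
    sd = √(between-plate variance + residual variance).  A single plate
    degrades to :func:`summarize_ols`; non-convergence falls back to an OLS
    summary of the plate means.  Both fallbacks are logged, never silent.
    """
    _check_level(level)
    if not isinstance(values, pd.DataFrame):
        values = pd.DataFrame(values, columns=["plate_id", "value"])
    df = values[["plate_id", "value"]].copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df = df[np.isfinite(df["value"])]
    if len(df) == 0:
        raise EmptyGroupError("no finite values to summarize")

    plates = df["plate_id"].unique()
    n_plates = len(plates)
    if n_plates == 1:
        logger.info("summarize_lmm: single plate; degrading to OLS")
        out = summarize_ols(df["value"], level)
        out["n_plates"] = 1
        out["method"] = "ols_intra"
        return out

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit, converged = None, False
        model = sm.MixedLM(
            df["value"].to_numpy(),
            np.ones((len(df), 1)),
            groups=df["plate_id"].to_numpy(),
        )
        # powell retry handles boundary fits (between-plate variance -> 0)
        # where the default gradient optimizer stalls
        for method in (None, "powell"):
            try:
                fit = model.fit(reml=True, **({"method": method} if method else {}))
            except Exception:
                continue
            converged = bool(getattr(fit, "converged", True)) and bool(
                np.isfinite(fit.params[0]) and np.isfinite(fit.bse[0])
            )
            if converged:
                break

    if fit is None or not converged:
        logger.warning(
            "summarize_lmm: mixed model did not converge; "
            "falling back to OLS on plate means"
        )
        plate_means = df.groupby("plate_id")["value"].mean()
        out = summarize_ols(plate_means, level)
        out["n"] = int(len(df))
        out["n_plates"] = n_plates
        out["method"] = "ols_inter"
        return out

    mean = float(fit.params[0])
    se = float(fit.bse[0])
    var_between = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    tcrit = float(stats.t.ppf((1 + level) / 2, df=n_plates - 1))
    return {
        "mean": mean,
        "sd": float(np.sqrt(var_between + var_resid)),
        "ci_low": mean - tcrit * se,
        "ci_high": mean + tcrit * se,
        "n": int(len(df)),
        "n_plates": n_plates,
        "method": "lmm_inter",
        "var_between": var_between,
        "var_resid": var_resid,
    }


def get_energetics_summary(
    records: EnergeticsResult | pd.DataFrame,
    level: float = 0.95,
    method: str = "auto",
) -> pd.DataFrame:
    """Summarize per-well JATP by experimental group and quantity.

    ``method``: ``"auto"`` uses intra-plate OLS when the records come from a
    single plate and the mixed model when from several; ``"ols"`` and
    ``"lmm"`` force the summarizer.  Returns a tidy DataFrame with columns
    group, quantity, mean, sd, ci_low, ci_high, n_wells, n_plates, level,
    method.
    """
    if method not in ("auto", "ols", "lmm"):
        raise ValidationError("method must be auto, ols or lmm")
    data = records.data if isinstance(records, EnergeticsResult) else records
    if len(data) == 0:
        raise EmptyGroupError("no energetics records to summarize")

    rows = []
    for group, g in data.groupby("exp_group", sort=True):
        for quantity in ENERGETICS_QUANTITIES:
            vals = g[["plate_id", quantity]].rename(columns={quantity: "value"})
            vals = vals[np.isfinite(pd.to_numeric(vals["value"], errors="coerce"))]
            if len(vals) == 0:
                continue
            n_plates = vals["plate_id"].nunique()
            use_lmm = method == "lmm" or (method == "auto" and n_plates >= 2)
            if use_lmm:
                core = summarize_lmm(vals, level)
                method_used = core.get("method", "lmm_inter")
            else:
                core = summarize_ols(vals["value"], level)
                method_used = "ols_intra" if n_plates == 1 else "ols_inter"
            rows.append(
                GroupSummary(
                    exp_group=group,
                    quantity=quantity,
                    mean=core["mean"],
                    sd=core["sd"],
                    ci_low=core["ci_low"],
                    ci_high=core["ci_high"],
                    n_wells=core["n"],
                    n_plates=n_plates,
                    level=level,
                    method=method_used,
                )
            )
    return pd.DataFrame([asdict(r) for r in rows])


def rate_summary(
    table: RateTable,
    variance: str = "sd",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per (exp_group, assay_type, measurement) mean rate with variance band.

    One row per group × assay × measurement for each of OCR and ECAR;
    ``band_low``/``band_high`` are mean ± SD (``variance="sd"``) or the
    t-based CI (``variance="ci"``) from the applicable summarizer.
    ``time_min`` is the group-mean clock time of the measurement.
    """
    if variance not in ("sd", "ci"):
        raise ValidationError("variance must be 'sd' or 'ci'")
    _check_level(level)
    if len(table.data) == 0:
        raise EmptyGroupError("empty rate table")

    rows = []
    for (group, assay, meas), g in table.data.groupby(
        ["exp_group", "assay_type", "measurement"], sort=True
    ):
        n_plates = g["plate_id"].nunique()
        for measure in ("ocr", "ecar"):
            vals = g[["plate_id", measure]].rename(columns={measure: "value"})
            vals = vals[np.isfinite(vals["value"])]
            if len(vals) == 0:
                continue
            if n_plates >= 2:
                core = summarize_lmm(vals, level)
                method_used = core.get("method", "lmm_inter")
            else:
                core = summarize_ols(vals["value"], level)
                method_used = "ols_intra"
            if variance == "sd":
                sd = core["sd"]
                lo = core["mean"] - sd if np.isfinite(sd) else np.nan
                hi = core["mean"] + sd if np.isfinite(sd) else np.nan
            else:
                lo, hi = core["ci_low"], core["ci_high"]
            rows.append(
                {
                    "exp_group": group,
                    "assay_type": assay,
                    "measurement": meas,
                    "measure": measure,
                    "time_min": float(g["time_min"].mean()),
                    "mean": core["mean"],
                    "sd": core["sd"],
                    "band_low": lo,
                    "band_high": hi,
                    "n_wells": core["n"],
                    "n_plates": n_plates,
                    "level": level,
                    "variance": variance,
                    "method": method_used,
                }
            )
    return pd.DataFrame(rows)
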