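"""Efficiency-corrected relative quantification of qRT-PCR data.

Primer efficiency E (fold amplification per cycle) is estimated per
gene from a serial dilution series as E = 10^(-1/slope), slope being
the least-squares fit of Ct on log10(dilution).  Expression of a target
relative to the housekeeping reference (myosin in the original design)
uses the two-efficiency ratio

    R = E_ref^Ct_ref / E_target^Ct_target,

which reduces to the familiar 2^(Ct_ref - Ct_target) when both assays
amplify perfectly.  Technical replicates are averaged on the Ct scale
(Ct noise is approximately additive) within each biological replicate;
group means and standard errors are taken over biological replicates.
Observations with Ct above the censoring threshold (default 35 cycles)
or missing are below detection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError, SchemaError, UndefinedStatisticError

log = logging.getLogger("auxiaa")

#: Standard curve used for primer-efficiency estimation.
DILUTION_SERIES = (1, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64, 1 / 128)

CT_COLUMNS = ["gene", "sample_id", "bio_rep", "tech_rep", "ct"]
DEFAULT_MAX_CT = 35.0


@dataclass
class EfficiencyModel:
    """Standard-curve fit for one primer pair."""

    gene: str
    slope: float          # cycles per log10(dilution)
    intercept: float      # cycles at dilution 1
    efficiency: float     # fold amplification per cycle; NaN when invalid
    fit_r2: float
    valid: bool           # False when slope >= 0 (no meaningful amplification)


def fit_efficiency(dilutions, cts, gene: str = "") -> EfficiencyModel:
    """Fit a primer standard curve and derive the efficiency.

    Requires at least 3 non-censored points.  A non-negative slope is
    flagged invalid (efficiency NaN) rather than raising.
    """
    d = np.asarray(dilutions, dtype=float)
    c = np.asarray(cts, dtype=float)
    if np.any(d <= 0):
        raise InputError("dilution fractions must be positive")
    keep = np.isfinite(c)
    d, c = d[keep], c[keep]
    if len(d) < 3:
        raise InsufficientDataError(
            f"{gene or 'standard curve'}: need >=3 non-censored points, got {len(d)}"
        )
    x = np.log10(d)
    if np.allclose(c, c[0]) or np.ptp(x) == 0:
        slope, intercept, r2 = 0.0, float(np.mean(c)), 0.0
    else:
        fit = stats.linregress(x, c)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    valid = slope < 0
    eff = 10.0 ** (-1.0 / slope) if valid else float("nan")
    if not valid:
        log.warning("%s: invalid efficiency model (slope=%.4g >= 0)", gene or "curve", slope)
    return EfficiencyModel(gene=gene, slope=slope, intercept=intercept,
                           efficiency=eff, fit_r2=r2, valid=valid)


def relative_expression(
    ct_target: float, ct_ref: float, e_target: float = 2.0, e_ref: float = 2.0
) -> float:
    """Efficiency-corrected expression of a target relative to the
    reference: ``E_ref**Ct_ref / E_target**Ct_target``.

    A censored Ct (NaN) propagates to a NaN (censored) result.
    """
    for name, e in (("target", e_target), ("reference", e_ref)):
        if not (1.0 < e <= 2.2):
            raise InputError(f"{name} efficiency {e} outside (1, 2.2]")
    if not np.isfinite(ct_target) or not np.isfinite(ct_ref):
        return float("nan")
    if ct_target <= 0 or ct_ref <= 0:
        raise InputError("Ct values must be positive")
    # log-space to keep large Ct differences stable
    return math.exp(ct_ref * math.log(e_ref) - ct_target * math.log(e_target))


@dataclass
class ExpressionMatrix:
    """Relative expression per gene x sample group.

    ``replicates``: one row per (gene, group, bio_rep) with the
    efficiency-corrected expression value (NaN = below detection).
    ``summary``: per (gene, group) mean/SE over detected biological
    replicates and a ``below_detection`` flag set when every replicate
    is censored.
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame

    def values(self, gene: str, group: str) -> np.ndarray:
        rows = self.replicates
        v = rows.loc[(rows["gene"] == gene) & (rows["group"] == group), "expression"]
        return v.dropna().to_numpy()

    def group_mean(self, gene: str, group: str) -> float:
        s = self.summary
        row = s.loc[(s["gene"] == gene) & (s["group"] == group)]
        if row.empty:
            return float("nan")
        return float(row["mean"].iloc[0])


def sample_group(root_type, stage=None, treatment_time=None) -> str:
    """Canonical sample-group label.

    Induction samples group by time point (``t0``..); developmental
    samples by root type, optionally with a stage suffix.
    """
    if treatment_time is not None and not (isinstance(treatment_time, float) and np.isnan(treatment_time)):
        return f"t{int(treatment_time)}"
    rt = str(root_type)
    if stage is not None and not (isinstance(stage, float) and np.isnan(stage)) and str(stage) != "":
        return f"{rt}:{stage}"
    return rt


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"Ct table missing columns {missing}")


def aggregate_replicates(
    observations: pd.DataFrame,
    housekeeping: str,
    efficiencies: dict[str, float] | None = None,
    *,
    max_ct: float = DEFAULT_MAX_CT,
    assume_perfect_efficiency: bool = False,
) -> ExpressionMatrix:
    """Collapse a raw Ct table into an expression matrix.

    Pipeline per biological replicate: average technical Cts (censored
    readings dropped; all-censored means a censored replicate),
    normalize to the housekeeping Ct of the same sample, one expression
    value per biological replicate.  Samples whose housekeeping assay is
    censored are excluded with a warning.  ``efficiencies`` maps gene to
    per-cycle amplification E (default 2.0); ``assume_perfect_efficiency``
    forces E = 2 everywhere (classic delta-delta-Ct behaviour).
    """
    df = observations.copy()
    _require_columns(df, CT_COLUMNS)
    for optional in ("root_type", "stage", "treatment_time"):
        if optional not in df.columns:
            df[optional] = None
    if housekeeping not in set(df["gene"]):
        raise SchemaError(f"housekeeping gene {housekeeping!r} not present in Ct table")
    dup = df.duplicated(subset=["gene", "sample_id", "bio_rep", "tech_rep"])
    if dup.any():
        raise InputError("duplicate (gene, sample_id, bio_rep, tech_rep) observations")

    eff = dict(efficiencies or {})

    def e_of(gene: str) -> float:
        if assume_perfect_efficiency:
            return 2.0
        return float(eff.get(gene, 2.0))

    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df.loc[df["ct"] > max_ct, "ct"] = np.nan

    keys = ["gene", "sample_id", "root_type", "stage", "treatment_time", "bio_rep"]
    tech = (
        df.groupby(keys, dropna=False, sort=True)["ct"]
        .mean()  # NaN when every technical replicate is censored
        .reset_index()
    )

    hk = tech[tech["gene"] == housekeeping].set_index(["sample_id", "bio_rep"])["ct"]
    rows = []
    for _, row in tech[tech["gene"] != housekeeping].iterrows():
        key = (row["sample_id"], row["bio_rep"])
        if key not in hk.index:
            log.warning("sample %s bio_rep %s: no housekeeping measurement; excluded", *key)
            continue
        ct_ref = hk.loc[key]
        if not np.isfinite(ct_ref):
            log.warning("sample %s bio_rep %s: housekeeping censored; excluded", *key)
            continue
        expr = relative_expression(row["ct"], ct_ref, e_of(row["gene"]), e_of(housekeeping))
        rows.append(
            {
                "gene": row["gene"],
                "group": sample_group(row["root_type"], row["stage"], row["treatment_time"]),
                "root_type": row["root_type"],
                "stage": row["stage"],
                "treatment_time": row["treatment_time"],
                "bio_rep": row["bio_rep"],
                "expression": expr,
            }
        )
    reps = pd.DataFrame(rows)

    summaries = []
    for (gene, group), sub in reps.groupby(["gene", "group"], sort=True):
        vals = sub["expression"].dropna().to_numpy()
        below = len(vals) == 0
        summaries.append(
            {
                "gene": gene,
                "group": group,
                "root_type": sub["root_type"].iloc[0],
                "stage": sub["stage"].iloc[0],
                "n_detected": len(vals),
                "mean": float(np.mean(vals)) if not below else float("nan"),
                "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "below_detection": below,
            }
        )
    summary = pd.DataFrame(summaries)
    log.info(
        "expression matrix: %d genes x %d groups",
        summary["gene"].nunique() if not summary.empty else 0,
        summary["group"].nunique() if not summary.empty else 0,
    )
    return ExpressionMatrix(replicates=reps, summary=summary)


def transcript_share(expression: ExpressionMatrix, group: str) -> pd.Series:
    """Fraction of the family's summed transcript level contributed by
    each detected gene within one sample group; shares sum to 1."""
    s = expression.summary
    sub = s[(s["group"] == group) & (~s["below_detection"])]
    if sub.empty:
        raise UndefinedStatisticError(f"no detected genes in group {group!r}")
    total = sub["mean"].sum()
    return pd.Series(sub["mean"].to_numpy() / total, index=sub["gene"].to_numpy(), name="share")
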