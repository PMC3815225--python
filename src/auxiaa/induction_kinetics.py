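"""Classification of auxin-induction time courses.

Expression of each gene is followed over an auxin treatment at four
time points (t0 = untreated control, then 1, 2, 3 h) with three
biological replicates.  Each course is assigned one of four labels:

* ``A`` - sustained induction: some time point is significantly above
  the control and expression at t3 is still significantly above t0;
* ``B`` - transient induction: t1 or t2 is significantly above t0 and
  a later consecutive time point (t2 vs t1, or t3 vs t2) shows a
  significant decrease;
* ``not_inducible`` - neither pattern;
* ``below_detection`` - every time point censored.

When a course satisfies both definitions (rise, later significant dip,
t3 still elevated), B takes precedence: the significant decrease is
what defines the transient class.  Comparisons are the same two-sided
pooled-variance t-tests used for the tissue contrasts, at alpha = 0.05
per comparison by default.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .expression_stats import ttest_groups

log = logging.getLogger("auxiaa")

TIME_POINTS = (0, 1, 2, 3)  # hours
LABELS = ("A", "B", "not_inducible", "below_detection")


@dataclass
class InductionSeries:
    """Per-gene induction time course: replicate expression values per
    time point (NaN = censored replicate)."""

    gene: str
    values: dict[int, np.ndarray]   # hour -> replicate expression values

    def __post_init__(self) -> None:
        if tuple(sorted(self.values)) != TIME_POINTS:
            raise InsufficientDataError(
                f"{self.gene}: expected time points {TIME_POINTS}, got {sorted(self.values)}"
            )
        self.values = {t: np.asarray(v, dtype=float) for t, v in self.values.items()}

    def detected(self, t: int) -> np.ndarray:
        return self.values[t][np.isfinite(self.values[t])]

    @property
    def all_censored(self) -> bool:
        return all(len(self.detected(t)) == 0 for t in TIME_POINTS)


@dataclass
class InductionPattern:
    gene: str
    label: str
    comparisons: list[tuple[str, float, str]] = field(default_factory=list)
    # (comparison, p_value, direction) for each supporting test


def classify_induction(series: InductionSeries, alpha: float = 0.05) -> InductionPattern:
    """Assign the induction label for one gene's time course.

    Decision procedure: (1) all time points censored -> below_detection;
    (2) t-tests of t1,t2,t3 vs t0 and of t2 vs t1, t3 vs t2;
    (3) B when t1 or t2 is significantly increased over t0 AND a later
    consecutive comparison is significantly decreased; (4) otherwise A
    when some ti is significantly increased over t0 AND t3 is; (5) else
    not_inducible.  A fully censored non-control time point simply
    removes its comparisons; a time point with fewer than 2 detected
    replicates (but not zero) is a classification error.
    """
    if series.all_censored:
        return InductionPattern(series.gene, "below_detection")

    usable: dict[int, np.ndarray] = {}
    for t in TIME_POINTS:
        v = series.detected(t)
        if len(v) == 0:
            continue
        if len(v) < 2:
            raise InsufficientDataError(
                f"{series.gene}: {len(v)} replicate at t{t}; need >=2 for testing"
            )
        usable[t] = v
    if 0 not in usable:
        raise InsufficientDataError(f"{series.gene}: control time point t0 fully censored")

    comps: dict[tuple[int, int], tuple[float, str]] = {}
    records = []
    for ta, tb in [(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)]:
        if ta not in usable or tb not in usable:
            continue
        t, p = ttest_groups(usable[tb], usable[ta])
        direction = "increase" if np.mean(usable[tb]) > np.mean(usable[ta]) else "decrease"
        comps[(ta, tb)] = (p, direction)
        records.append((f"t{tb} vs t{ta}", p, direction))

    def sig_up(key) -> bool:
        return key in comps and comps[key][0] <= alpha and comps[key][1] == "increase"

    def sig_down(key) -> bool:
        return key in comps and comps[key][0] <= alpha and comps[key][1] == "decrease"

    early_rise = sig_up((0, 1)) or sig_up((0, 2))
    later_dip = sig_down((1, 2)) or sig_down((2, 3))
    any_rise = early_rise or sig_up((0, 3))

    if early_rise and later_dip:
        label = "B"
    elif any_rise and sig_up((0, 3)):
        label = "A"
    else:
        label = "not_inducible"
    return InductionPattern(series.gene, label, records)


def batch_classify(
    series_set: list[InductionSeries], alpha: float = 0.05
) -> tuple[dict[str, int], pd.DataFrame]:
    """Classify a set of time courses; returns per-label counts and a
    per-gene table.  Deterministic and independent of input order."""
    patterns = [classify_induction(s, alpha=alpha) for s in sorted(series_set, key=lambda s: s.gene)]
    counts = Counter(p.label for p in patterns)
    table = pd.DataFrame([{"gene": p.gene, "label": p.label} for p in patterns])
    log.info("induction labels: %s", dict(counts))
    return {label: counts.get(label, 0) for label in LABELS}, table


def series_from_expression(replicates: pd.DataFrame) -> list[InductionSeries]:
    """Build induction series from an expression-matrix replicate table
    whose groups are time points (``t0``..``t3``)."""
    out = []
    for gene, sub in replicates.groupby("gene", sort=True):
        values = {}
        for t in TIME_POINTS:
            vals = sub.loc[sub["group"] == f"t{t}", "expression"].to_numpy(dtype=float)
            values[t] = vals if len(vals) else np.array([np.nan])
        out.append(InductionSeries(gene=gene, values=values))
    return out
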