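"""Differential expression, root-type hierarchy scoring, and paralog
expression correlation.

Differential calls are classical (pooled-variance) two-sided Student
t-tests on per-biological-replicate expression values, reported in
three significance tiers (p <= 0.05 / 0.01 / 0.001, the color tiers of
the original summary figures); no multiple-testing adjustment is
applied by default, with optional Benjamini-Hochberg.

The hierarchy score counts how many significant root-type contrasts
agree with a fixed expression ranking (crown > seminal > primary >
lateral for this family).  Paralog pairs are compared by ordinary
least squares of one member's group means on the other's, with the
R-squared > 0.5 at p <= 0.01 significance rule.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError
from .io import GeneMeta
from .qpcr_quant import ExpressionMatrix

log = logging.getLogger("auxiaa")

TIERS = ("ns", "0.05", "0.01", "0.001")


def significance_tier(p: float, alpha_tiers=(0.05, 0.01, 0.001)) -> str:
    """Strictest tier whose threshold the p-value meets (``ns`` if none)."""
    tier = "ns"
    for a in sorted(alpha_tiers, reverse=True):
        if p <= a:
            tier = f"{a:g}"
    return tier


@dataclass
class DifferentialCall:
    gene: str
    group_a: str
    group_b: str
    root_type_a: str | None
    root_type_b: str | None
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    tier: str              # ns | 0.05 | 0.01 | 0.001
    direction: str         # a_higher | b_higher

    @property
    def significant(self) -> bool:
        return self.tier != "ns"


def ttest_groups(a: np.ndarray, b: np.ndarray, pooled: bool = True) -> tuple[float, float]:
    """Two-sided t-test; pooled variance (classical Student) by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate zero-variance samples: identical means are a null
        # result, distinct means an unambiguous difference
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def pairwise_ttests(
    expression: ExpressionMatrix,
    group_pairs: list[tuple[str, str]],
    *,
    alpha_tiers=(0.05, 0.01, 0.001),
    pooled: bool = True,
    bh_correct: bool = False,
    genes: list[str] | None = None,
) -> list[DifferentialCall]:
    """Tiered two-sided t-tests for every gene over the listed group
    pairs.  Groups with fewer than 2 detected biological replicates are
    skipped with a warning.  ``bh_correct`` applies Benjamini-Hochberg
    across all computed tests before tier assignment.
    """
    reps = expression.replicates
    gene_list = genes if genes is not None else sorted(reps["gene"].unique())
    root_of = {}
    for _, row in expression.summary.iterrows():
        root_of[row["group"]] = row.get("root_type")
    raw: list[DifferentialCall] = []
    pvals: list[float] = []
    for gene in gene_list:
        for ga, gb in group_pairs:
            va = expression.values(gene, ga)
            vb = expression.values(gene, gb)
            if len(va) < 2 or len(vb) < 2:
                log.warning("%s: %s vs %s skipped (<2 replicates)", gene, ga, gb)
                continue
            t, p = ttest_groups(va, vb, pooled=pooled)
            ma, mb = float(np.mean(va)), float(np.mean(vb))
            raw.append(
                DifferentialCall(
                    gene=gene, group_a=ga, group_b=gb,
                    root_type_a=root_of.get(ga), root_type_b=root_of.get(gb),
                    mean_a=ma, mean_b=mb, t_statistic=t, p_value=p,
                    tier="ns", direction="a_higher" if ma >= mb else "b_higher",
                )
            )
            pvals.append(p)
    padj = _bh(pvals) if bh_correct else pvals
    for call, p in zip(raw, padj):
        call.tier = significance_tier(p, alpha_tiers)
    return raw


def _bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj.tolist()


# ---------------------------------------------------------------------------
# hierarchy scoring

@dataclass
class HierarchyScore:
    order: tuple[str, ...]
    n_consistent: int
    n_total: int

    @property
    def fraction(self) -> float | None:
        return self.n_consistent / self.n_total if self.n_total > 0 else None


def score_hierarchy(
    calls: list[DifferentialCall],
    order: tuple[str, ...],
    *,
    per_stage: bool = False,
) -> HierarchyScore:
    """Consistency of significant root-type contrasts with a fixed
    expression ranking (``order``, highest first).

    A significant call is consistent when the root type ranked higher
    in ``order`` has the higher mean.  By default comparisons against a
    multi-stage root type collapse to one pattern per (gene, root-type
    pair): consistent iff consistent at >=1 stage and contradicted at
    none.  ``per_stage`` counts every significant call separately.
    """
    rank = {rt: i for i, rt in enumerate(order)}
    sig = [c for c in calls if c.significant]
    for c in sig:
        for rt in (c.root_type_a, c.root_type_b):
            if rt not in rank:
                raise ValidationError(f"root type {rt!r} not in hierarchy order {order}")

    def consistent(c: DifferentialCall) -> bool:
        higher_rt = c.root_type_a if rank[c.root_type_a] < rank[c.root_type_b] else c.root_type_b
        higher_mean_rt = c.root_type_a if c.mean_a >= c.mean_b else c.root_type_b
        return higher_rt == higher_mean_rt

    if per_stage:
        n_total = len(sig)
        n_cons = sum(consistent(c) for c in sig)
    else:
        patterns: dict[tuple, list[bool]] = {}
        for c in sig:
            key = (c.gene, tuple(sorted((c.root_type_a, c.root_type_b))))
            patterns.setdefault(key, []).append(consistent(c))
        n_total = len(patterns)
        n_cons = sum(all(v) and any(v) for v in patterns.values())
    return HierarchyScore(order=tuple(order), n_consistent=n_cons, n_total=n_total)


# ---------------------------------------------------------------------------
# paralog correlation

@dataclass
class ParalogCorrelation:
    pair: tuple[str, str]
    r2: float
    p_value: float
    significant: bool
    higher_member: str
    subgenome_of_higher: str
    n_groups: int


def paralog_correlation(
    expression: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    metadata: list[GeneMeta] | None = None,
    *,
    groups: list[str] | None = None,
    r2_threshold: float = 0.5,
    alpha: float = 0.01,
) -> list[ParalogCorrelation]:
    """Expression correlation between retained duplicate gene pairs.

    For each pair, the group means of member b are regressed on those
    of member a across the sample groups where both are detected (at
    least 3 required); R-squared and the zero-slope p-value come from
    ordinary least squares.  ``significant`` applies the R^2 >
    ``r2_threshold`` and p <= ``alpha`` rule.  The higher-expressed
    member and its subgenome (from ``metadata``) are reported.
    """
    s = expression.summary
    sub_of = {g.gene_name: g.subgenome for g in (metadata or [])}
    out = []
    for a, b in pairs:
        sa = s[(s["gene"] == a) & (~s["below_detection"])].set_index("group")["mean"]
        sb = s[(s["gene"] == b) & (~s["below_detection"])].set_index("group")["mean"]
        shared = sorted(set(sa.index) & set(sb.index))
        if groups is not None:
            shared = [g for g in shared if g in set(groups)]
        if len(shared) < 3:
            raise UndefinedStatisticError(
                f"pair ({a},{b}): only {len(shared)} shared detected groups (need >=3)"
            )
        x = sa.loc[shared].to_numpy()
        y = sb.loc[shared].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedStatisticError(f"pair ({a},{b}): zero variance in a member's profile")
        fit = stats.linregress(x, y)
        r2 = float(fit.rvalue**2)
        p = float(fit.pvalue)
        higher = a if float(np.mean(x)) >= float(np.mean(y)) else b
        out.append(
            ParalogCorrelation(
                pair=(a, b),
                r2=r2,
                p_value=p,
                significant=(r2 > r2_threshold and p <= alpha),
                higher_member=higher,
                subgenome_of_higher=sub_of.get(higher, "unassigned"),
                n_groups=len(shared),
            )
        )
    return out


def calls_table(calls: list[DifferentialCall]) -> pd.DataFrame:
    color = {"ns": "", "0.05": "red", "0.01": "yellow", "0.001": "green"}
    return pd.DataFrame(
        [
            {
                "gene": c.gene, "group_a": c.group_a, "group_b": c.group_b,
                "mean_a": c.mean_a, "mean_b": c.mean_b,
                "t_statistic": c.t_statistic, "p_value": c.p_value,
                "tier": c.tier, "tier_color": color[c.tier], "direction": c.direction,
            }
            for c in calls
        ]
    )
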