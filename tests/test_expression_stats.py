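import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from auxiaa.errors import UndefinedStatisticError, ValidationError
from auxiaa.expression_stats import (
    DifferentialCall,
    pairwise_ttests,
    paralog_correlation,
    score_hierarchy,
    significance_tier,
    ttest_groups,
)
from auxiaa.io import load_family_metadata
from auxiaa.qpcr_quant import ExpressionMatrix, aggregate_replicates
from auxiaa.synthetic_data import simulate_ct_table

from oracles import ols_r2


def _matrix(values: dict[str, dict[str, list[float]]]) -> ExpressionMatrix:
    """Expression matrix from {gene: {group: [per-replicate values]}}."""
    reps, summ = [], []
    for gene, per_group in values.items():
        for group, vals in per_group.items():
            for b, v in enumerate(vals, start=1):
                reps.append(
                    {"gene": gene, "group": group, "root_type": group.split(":")[0],
                     "stage": None, "treatment_time": None, "bio_rep": b,
                     "expression": v}
                )
            arr = np.asarray(vals, dtype=float)
            det = arr[np.isfinite(arr)]
            summ.append(
                {"gene": gene, "group": group, "root_type": group.split(":")[0],
                 "stage": None, "n_detected": len(det),
                 "mean": float(det.mean()) if len(det) else float("nan"),
                 "se": float("nan"), "below_detection": len(det) == 0}
            )
    return ExpressionMatrix(pd.DataFrame(reps), pd.DataFrame(summ))


class TestPairwiseTTests:
    def test_worked_example(self):
        t, p = ttest_groups([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_groups_not_significant(self):
        em = _matrix({"g": {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}})
        (call,) = pairwise_ttests(em, [("a", "b")])
        assert call.t_statistic == 0.0
        assert call.tier == "ns"

    def test_symmetry(self):
        em = _matrix({"g": {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]}})
        (ab,) = pairwise_ttests(em, [("a", "b")])
        (ba,) = pairwise_ttests(em, [("b", "a")])
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.tier == ba.tier
        assert {ab.direction, ba.direction} == {"a_higher", "b_higher"}

    def test_small_group_skipped_with_warning(self, caplog):
        em = _matrix({"g": {"a": [1.0], "b": [2.0, 3.0]}})
        assert pairwise_ttests(em, [("a", "b")]) == []
        assert any("skipped" in r.message for r in caplog.records)

    def test_tier_assignment(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.04) == "0.05"
        assert significance_tier(0.009) == "0.01"
        assert significance_tier(0.0005) == "0.001"

    def test_bh_correction_weakens_calls(self):
        rng = np.random.default_rng(3)
        values = {
            f"g{i}": {"a": list(rng.normal(0, 1, 5)), "b": list(rng.normal(0.5, 1, 5))}
            for i in range(20)
        }
        em = _matrix(values)
        raw = pairwise_ttests(em, [("a", "b")])
        adj = pairwise_ttests(em, [("a", "b")], bh_correct=True)
        assert sum(c.significant for c in adj) <= sum(c.significant for c in raw)


def _call(gene, rt_a, rt_b, mean_a, mean_b, tier="0.05"):
    return DifferentialCall(
        gene=gene, group_a=rt_a, group_b=rt_b, root_type_a=rt_a.split(":")[0],
        root_type_b=rt_b.split(":")[0], mean_a=mean_a, mean_b=mean_b,
        t_statistic=0.0, p_value=0.01, tier=tier,
        direction="a_higher" if mean_a >= mean_b else "b_higher",
    )


ORDER = ("crown", "seminal", "primary", "lateral")


class TestScoreHierarchy:
    def test_fully_consistent(self):
        calls = [_call(f"g{i}", "crown", "primary", 5.0, 1.0) for i in range(4)]
        score = score_hierarchy(calls, ORDER)
        assert (score.n_consistent, score.n_total) == (4, 4)
        assert score.fraction == 1.0

    def test_enumerated_half_consistent(self):
        calls = [
            _call("g", "crown", "primary", 5.0, 1.0),    # consistent
            _call("g", "seminal", "lateral", 5.0, 1.0),  # consistent
            _call("g", "lateral", "primary", 5.0, 1.0),  # contradicts order
            _call("g", "primary", "seminal", 5.0, 1.0),  # contradicts order
        ]
        score = score_hierarchy(calls, ORDER)
        assert (score.n_consistent, score.n_total) == (2, 4)
        assert score.fraction == 0.5

    def test_no_significant_calls(self):
        calls = [_call("g", "crown", "primary", 5.0, 1.0, tier="ns")]
        score = score_hierarchy(calls, ORDER)
        assert score.n_total == 0 and score.fraction is None

    def test_order_invariance_and_ns_noop(self):
        calls = [
            _call("g1", "crown", "primary", 5.0, 1.0),
            _call("g2", "primary", "lateral", 2.0, 1.0),
        ]
        base = score_hierarchy(calls, ORDER)
        shuffled = score_hierarchy(calls[::-1], ORDER)
        with_ns = score_hierarchy(calls + [_call("g3", "crown", "lateral", 9, 1, "ns")], ORDER)
        assert (base.n_consistent, base.n_total) == (shuffled.n_consistent, shuffled.n_total)
        assert (base.n_consistent, base.n_total) == (with_ns.n_consistent, with_ns.n_total)

    def test_multi_stage_collapsing(self):
        # significant at one stage, never contradicted -> one consistent pattern
        calls = [
            _call("g", "crown", "primary:1-2cm", 5.0, 1.0),
            _call("g", "crown", "primary:4-8cm", 5.0, 1.0, tier="ns"),
        ]
        score = score_hierarchy(calls, ORDER)
        assert (score.n_consistent, score.n_total) == (1, 1)
        # contradicted at another stage -> counted once, inconsistent
        calls.append(_call("g", "crown", "primary:8-16cm", 1.0, 5.0))
        score = score_hierarchy(calls, ORDER)
        assert (score.n_consistent, score.n_total) == (0, 1)
        # per-stage mode counts each significant call
        score = score_hierarchy(calls, ORDER, per_stage=True)
        assert (score.n_consistent, score.n_total) == (1, 2)

    def test_unknown_root_type_rejected(self):
        with pytest.raises(ValidationError, match="brace"):
            score_hierarchy([_call("g", "brace", "crown", 2.0, 1.0)], ORDER)

    def test_planted_hierarchy_recovered(self):
        from auxiaa.synthetic_data import root_type_design

        fracs = []
        for run in range(20):
            groups, conc = root_type_design(n_genes=10, seed=100 + run)
            ct, _ = simulate_ct_table(
                groups, conc, sigma_bio=0.3, sigma_tech=0.1, seed=200 + run
            )
            em = aggregate_replicates(ct, "myosin")
            gs = sorted(em.summary["group"].unique())
            calls = pairwise_ttests(em, list(itertools.combinations(gs, 2)))
            calls = [c for c in calls if c.root_type_a != c.root_type_b]
            score = score_hierarchy(calls, ORDER)
            if score.n_total:
                fracs.append(score.fraction)
        assert np.mean(fracs) >= 0.9


class TestParalogCorrelation:
    def test_identical_profiles(self):
        em = _matrix({
            "a": {"g1": [1.0], "g2": [2.0], "g3": [3.0], "g4": [4.0]},
            "b": {"g1": [1.0], "g2": [2.0], "g3": [3.0], "g4": [4.0]},
        })
        (pc,) = paralog_correlation(em, [("a", "b")])
        assert pc.r2 == pytest.approx(1.0)

    def test_constant_profile_rejected(self):
        em = _matrix({
            "a": {"g1": [1.0], "g2": [2.0], "g3": [3.0]},
            "b": {"g1": [2.0], "g2": [2.0], "g3": [2.0]},
        })
        with pytest.raises(UndefinedStatisticError, match="zero variance"):
            paralog_correlation(em, [("a", "b")])

    def test_worked_example_against_least_squares_oracle(self):
        x, y = (1.0, 2.0, 3.0, 4.0), (1.0, 3.0, 2.0, 4.0)
        em = _matrix({
            "a": {f"g{i}": [v] for i, v in enumerate(x)},
            "b": {f"g{i}": [v] for i, v in enumerate(y)},
        })
        (pc,) = paralog_correlation(em, [("a", "b")])
        assert pc.r2 == pytest.approx(0.64)
        assert pc.r2 == pytest.approx(ols_r2(x, y))

    def test_too_few_shared_groups_rejected(self):
        em = _matrix({"a": {"g1": [1.0], "g2": [2.0]}, "b": {"g1": [1.0], "g2": [2.0]}})
        with pytest.raises(UndefinedStatisticError, match="shared"):
            paralog_correlation(em, [("a", "b")])

    def test_higher_member_and_subgenome(self):
        meta = load_family_metadata()
        em = _matrix({
            "ZmIAA1": {"g1": [10.0], "g2": [20.0], "g3": [30.0]},
            "ZmIAA8": {"g1": [1.0], "g2": [2.0], "g3": [3.0]},
        })
        (pc,) = paralog_correlation(em, [("ZmIAA1", "ZmIAA8")], metadata=meta)
        assert pc.higher_member == "ZmIAA1"
        assert pc.subgenome_of_higher == "1"
        assert pc.significant  # r2 = 1, p well below 0.01

    @given(
        scale=st.floats(0.1, 50),
        shift=st.floats(-5, 5),
    )
    def test_r2_affine_invariance(self, scale, shift):
        x = (1.0, 2.0, 3.0, 4.0)
        y = (1.0, 3.0, 2.0, 4.0)
        em1 = _matrix({
            "a": {f"g{i}": [v] for i, v in enumerate(x)},
            "b": {f"g{i}": [v] for i, v in enumerate(y)},
        })
        em2 = _matrix({
            "a": {f"g{i}": [v * scale + shift] for i, v in enumerate(x)},
            "b": {f"g{i}": [v] for i, v in enumerate(y)},
        })
        (p1,) = paralog_correlation(em1, [("a", "b")])
        (p2,) = paralog_correlation(em2, [("a", "b")])
        assert p1.r2 == pytest.approx(p2.r2, rel=1e-9)
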