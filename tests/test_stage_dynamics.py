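"""Regulation calls, down:up ratio summaries and m6A-stratified percentages."""

import math

import numpy as np
import pandas as pd
import pytest

from m6amir import (
    CALL_DOWN,
    CALL_NOT_COMPUTABLE,
    CALL_UNCHANGED,
    CALL_UP,
    RegulationCall,
    StageMatrix,
    call_regulation,
    summarize_ratios,
    threshold_sensitivity,
)
from m6amir.stage_dynamics import StageError


def matrix_from(genes, ref, cmp_, ref_label="P1", cmp_label="P23"):
    frame = pd.DataFrame({ref_label: ref, cmp_label: cmp_}, index=genes)
    return StageMatrix(values=frame, reference_stage=ref_label)


class TestCallRegulation:
    def test_exact_halving_is_down(self):
        m = matrix_from(["g"], [10.0], [5.0])
        (c,) = call_regulation(m, "P23", fc_threshold=1.5)
        assert c.log2_ratio == pytest.approx(-1.0)
        assert c.call == CALL_DOWN

    def test_identity_is_unchanged(self):
        m = matrix_from(["g"], [10.0], [10.0])
        for fc in (1.2, 1.5, 2.0):
            (c,) = call_regulation(m, "P23", fc_threshold=fc)
            assert c.call == CALL_UNCHANGED

    def test_threshold_one_leaves_no_unchanged_except_ties(self):
        rng = np.random.default_rng(0)
        ref = rng.lognormal(3, 0.5, 200)
        cmp_ = rng.lognormal(3, 0.5, 200)
        m = matrix_from([f"g{i}" for i in range(200)], ref, cmp_)
        calls = call_regulation(m, "P23", fc_threshold=1.0)
        for c, r, v in zip(calls, ref, cmp_):
            expected = CALL_DOWN if v < r else (CALL_UP if v > r else CALL_UNCHANGED)
            assert c.call == expected

    def test_zero_reference_not_computable(self):
        m = matrix_from(["a", "b"], [0.0, 4.0], [3.0, 8.0])
        calls = call_regulation(m, "P23", pseudocount=0.0)
        assert calls[0].call == CALL_NOT_COMPUTABLE
        assert calls[1].call == CALL_UP
        with_pc = call_regulation(m, "P23", pseudocount=1.0)
        assert with_pc[0].call == CALL_UP  # log2(4/1) = 2

    def test_zero_comparison_is_unbounded_decrease(self):
        m = matrix_from(["g"], [10.0], [0.0])
        (c,) = call_regulation(m, "P23")
        assert c.call == CALL_DOWN and c.log2_ratio == -math.inf

    def test_counts_conserved_and_threshold_monotone(self):
        rng = np.random.default_rng(1)
        n = 300
        m = matrix_from(
            [f"g{i}" for i in range(n)],
            rng.lognormal(3, 0.5, n),
            rng.lognormal(3, 0.8, n),
        )
        sens = threshold_sensitivity(m, "P23", thresholds=(1.2, 1.5, 2.0))
        totals = sens[["n_down", "n_up", "n_unchanged", "n_not_computable"]].sum(axis=1)
        assert (totals == n).all()
        assert sens["n_down"].is_monotonic_decreasing
        assert sens["n_up"].is_monotonic_decreasing

    def test_bad_stage_arguments_rejected(self):
        m = matrix_from(["g"], [1.0], [2.0])
        with pytest.raises(StageError):
            call_regulation(m, "P1")
        with pytest.raises(StageError):
            call_regulation(m, "nope")

    def test_negative_abundance_rejected(self):
        with pytest.raises(StageError):
            matrix_from(["g"], [-1.0], [2.0])


def calls_from_counts(n_down, n_up, prefix, m6a_status, modified):
    calls = []
    for i in range(n_down):
        g = f"{prefix}d{i}"
        calls.append(RegulationCall(g, -2.0, CALL_DOWN))
        m6a_status[g] = modified
    for i in range(n_up):
        g = f"{prefix}u{i}"
        calls.append(RegulationCall(g, 2.0, CALL_UP))
        m6a_status[g] = modified
    return calls


class TestSummarizeRatios:
    def test_constructed_count_arithmetic(self):
        status = {}
        a = calls_from_counts(25, 4, "a", status, True)
        b = calls_from_counts(8, 4, "b", status, True)
        sa, sb, fold = summarize_ratios(a, b, status)
        assert sa.down_up_ratio == pytest.approx(6.25)
        assert sb.down_up_ratio == pytest.approx(2.0)
        assert fold == pytest.approx(3.125)

    def test_stratified_percentage_rendering(self):
        """25 down / 4 up in the m6A stratum renders 86.21% down."""
        status = {}
        a = calls_from_counts(25, 4, "m", status, True) + calls_from_counts(
            34, 13, "u", status, False
        )
        sa, _, _ = summarize_ratios(a, a, status)
        assert sa.stratified_pct_down["m6a_modified"] == 86.21
        assert sa.stratified_pct_down["unmodified"] == pytest.approx(72.34)

    def test_identical_call_lists_fold_one(self):
        status = {}
        a = calls_from_counts(10, 5, "a", status, True)
        _, _, fold = summarize_ratios(a, a, status)
        assert fold == pytest.approx(1.0)

    def test_no_up_calls_flags_infinite_ratio(self):
        status = {}
        a = calls_from_counts(10, 0, "a", status, True)
        b = calls_from_counts(3, 2, "b", status, True)
        sa, sb, fold = summarize_ratios(a, b, status)
        assert math.isinf(sa.down_up_ratio) and not sa.ratio_defined
        assert math.isnan(fold)

    def test_unchanged_excluded_from_percentage(self):
        status = {"d": True, "u": True, "x": True}
        calls = [
            RegulationCall("d", -2.0, CALL_DOWN),
            RegulationCall("u", 2.0, CALL_UP),
            RegulationCall("x", 0.1, CALL_UNCHANGED),
        ]
        s, _, _ = summarize_ratios(calls, calls, status)
        assert s.stratified_pct_down["m6a_modified"] == 50.0
        assert s.n_unchanged == 1

    def test_empty_call_list_rejected(self):
        with pytest.raises(StageError):
            summarize_ratios([], [], {})


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_bernoulli_planted_fractions_recovered(self, seed):
        """Recovered stratified pct_down equals the realized planted fraction
        and sits inside the binomial 95% CI of the planted probability."""
        from m6amir import SimulationConfig, simulate_all

        cfg = SimulationConfig(rng_seed=seed, n_genes=400, n_mirnas=10,
                               n_full_match=1, n_partial_match=1)
        res = simulate_all(cfg)
        calls = call_regulation(res.matrix, "S1", fc_threshold=1.5)
        planted = res.regulation_truth["S1"]
        assert all(c.call == planted[c.gene_id] for c in calls)
        status = {g: t.m6a_modified_target for g, t in res.gene_truth.items()}
        targets = [c for c in calls if res.gene_truth[c.gene_id].is_target]
        s, _, _ = summarize_ratios(targets, calls, status)
        for label, f in (("m6a_modified", cfg.f_down_m6a), ("unmodified", cfg.f_down_non_m6a)):
            n = sum(
                1 for c in targets
                if status[c.gene_id] == (label == "m6a_modified")
            )
            half = 196 * math.sqrt(f * (1 - f) / n)  # 1.96 * 100 * se
            assert abs(s.stratified_pct_down[label] - 100 * f) <= half
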