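"""Exact overlap percentages and the two-sample enrichment-score comparison."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from m6amir import (
    GeneAnnotation,
    compare_scores,
    overlap,
    round_half_up,
    stratified_overlap_report,
)
from m6amir.overlap_stats import StatsError


def pooled_t_oracle(g1, g2):
    """Textbook two-sample pooled-variance t: the independent oracle."""
    g1, g2 = np.asarray(g1, float), np.asarray(g2, float)
    n1, n2 = len(g1), len(g2)
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    t = (g1.mean() - g2.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestOverlap:
    @pytest.mark.parametrize(
        "n_a,n_inter,expected",
        [
            (894, 270, "30.20"),  # miR-133a targets vs m6A-modified genes
            (416, 102, "24.52"),  # miR-499 analogue
        ],
    )
    def test_published_style_percentages(self, n_a, n_inter, expected):
        a = {f"g{i}" for i in range(n_a)}
        b = {f"g{i}" for i in range(n_inter)} | {f"x{i}" for i in range(50)}
        s = overlap(a, b)
        assert (s.n_a, s.n_intersection) == (n_a, n_inter)
        assert s.pct_rendered == expected

    def test_containment_is_100(self):
        s = overlap({"a", "b"}, {"a", "b", "c"})
        assert s.pct_rendered == "100.00"

    def test_empty_set_a_rejected(self):
        with pytest.raises(StatsError, match="empty"):
            overlap(set(), {"a"})

    def test_half_up_rounding_is_exact_rational(self):
        # 1/8 of 100% = 12.5 rounds *up* at 2 dp only in half-up semantics
        assert round_half_up(Fraction(100, 800) * 100) == 12.50
        assert round_half_up(Fraction(1, 16) * 100) == 6.25
        assert round_half_up(Fraction(1, 3) * 100) == 33.33
        assert round_half_up(Fraction(25, 1000) * 1) == 0.03  # 0.025 -> 0.03 half-up


class TestCompareScores:
    def test_identical_groups_degenerate(self):
        r = compare_scores([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (r.t_stat, r.p_two_sided) == (0.0, 1.0)

    def test_permutation_invariance(self):
        r = compare_scores([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_two_sided == pytest.approx(1.0)

    def test_matches_pooled_oracle(self):
        g1 = [2.1, 2.9, 3.0, 2.5]
        g2 = [1.0, 1.4, 1.2, 0.9]
        t, df, p = pooled_t_oracle(g1, g2)
        r = compare_scores(g1, g2, variant="pooled")
        assert r.t_stat == pytest.approx(t)
        assert r.df == df == 6
        assert r.p_two_sided == pytest.approx(p)
        # frozen from the oracle formula
        assert r.t_stat == pytest.approx(6.420, abs=1e-3)
        assert r.p_two_sided == pytest.approx(0.000677, abs=2e-5)

    def test_sign_follows_mean_difference_and_swap(self):
        g1, g2 = [3.0, 4.0, 5.0], [1.0, 2.0, 2.5]
        a = compare_scores(g1, g2)
        b = compare_scores(g2, g1)
        assert a.t_stat > 0 and b.t_stat == pytest.approx(-a.t_stat)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(2, 1, 20), rng.normal(1, 1, 20)
        base = compare_scores(g1, g2)
        shifted = compare_scores(g1 + 5.0, g2 + 5.0)
        scaled = compare_scores(g1 * 3.0, g2 * 3.0)
        assert shifted.t_stat == pytest.approx(base.t_stat)
        assert scaled.t_stat == pytest.approx(base.t_stat)
        assert shifted.p_two_sided == pytest.approx(base.p_two_sided)

    def test_welch_variant_df(self):
        g1 = [1.0, 2.0, 3.0, 4.0]
        g2 = [10.0, 30.0]
        r = compare_scores(g1, g2, variant="welch")
        assert r.variant == "welch"
        assert r.df < 4  # Welch df is fractional and below pooled here

    def test_small_groups_rejected(self):
        with pytest.raises(StatsError, match="n >= 2"):
            compare_scores([1.0], [1.0, 2.0])


def _ann(gene, target, modified):
    return GeneAnnotation(
        gene_id=gene,
        is_target=target,
        m6a_in_gene_set=modified,
        ggach_in_utr=modified,
        motif_overlaps_site=False,
        m6a_modified_target=target and modified,
    )


class TestStratifiedReport:
    def test_planted_overlap_and_shift_recovered(self):
        rng = np.random.default_rng(42)
        anns, scores = [], {}
        for i in range(500):
            modified = i < 150  # planted 30% overlap
            g = f"g{i}"
            anns.append(_ann(g, True, modified))
            scores[g] = float(rng.normal(2.0 + (1.0 if modified else 0.0), 1.0))
        rep = stratified_overlap_report(anns, scores)
        assert rep.overlap_summary.n_a == 500
        assert rep.overlap_summary.n_intersection == 150
        assert rep.overlap_summary.pct_rendered == "30.00"
        assert rep.comparison_computable
        assert rep.comparison.p_two_sided < 0.01
        assert rep.comparison.mean1 > rep.comparison.mean2

    def test_all_modified_marks_not_computable(self):
        anns = [_ann(f"g{i}", True, True) for i in range(10)]
        scores = {f"g{i}": float(i) for i in range(10)}
        rep = stratified_overlap_report(anns, scores)
        assert not rep.comparison_computable
        assert rep.comparison is None
        assert rep.overlap_summary.pct_rendered == "100.00"

    def test_unscored_targets_logged_not_dropped_from_overlap(self):
        anns = [_ann("a", True, True), _ann("b", True, False), _ann("c", True, False)]
        rep = stratified_overlap_report(anns, {"a": 1.0})
        assert rep.n_unscored == 2
        assert rep.overlap_summary.n_a == 3
        assert not rep.comparison_computable

    def test_null_type_one_error_controlled(self):
        """Empirical alpha at 0.05 within its binomial 95% CI under delta = 0."""
        rng = np.random.default_rng(7)
        n_reps, n = 400, 40
        rejections = 0
        for _ in range(n_reps):
            r = compare_scores(rng.normal(2, 1, n), rng.normal(2, 1, n))
            rejections += r.p_two_sided < 0.05
        lo = 0.05 - 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
        hi = 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
        assert lo <= rejections / n_reps <= hi
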