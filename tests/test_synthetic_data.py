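"""Planted-truth generators: exactness, determinism and degenerate branches."""

import filecmp

import numpy as np
import pytest

from m6amir import (
    GGACH,
    MATCH_FULL,
    MATCH_NONE,
    MATCH_PARTIAL,
    RRACH,
    SimulationConfig,
    gen_mirna_catalogue,
    gen_scores,
    gen_timecourse,
    gen_utr_genome,
    scan_motif,
    screen_catalogue,
    simulate_all,
    write_simulation,
)
from m6amir.mirna_screen import extract_seed
from m6amir.seqcore import NucleotideSequence, reverse_complement


class TestMirnaCatalogue:
    def test_planted_classes_realized_in_sequence(self):
        cfg = SimulationConfig(rng_seed=7, n_mirnas=139, n_full_match=1, n_partial_match=9)
        mirnas, truth = gen_mirna_catalogue(cfg)
        assert sorted(truth.values()).count(MATCH_FULL) == 1
        assert sorted(truth.values()).count(MATCH_PARTIAL) == 9
        for m in mirnas:
            site = reverse_complement(extract_seed(m))
            site = NucleotideSequence("s", site.residues)
            has_g = bool(scan_motif(site, GGACH))
            has_r = bool(scan_motif(site, RRACH))
            cls = truth[m.name]
            assert has_g == (cls == MATCH_FULL)
            assert has_r == (cls != MATCH_NONE)

    def test_clean_catalogue_all_none(self):
        cfg = SimulationConfig(rng_seed=3, n_mirnas=20, n_full_match=0, n_partial_match=0)
        mirnas, truth = gen_mirna_catalogue(cfg)
        assert set(truth.values()) == {MATCH_NONE}
        assert all(r.match_class == MATCH_NONE for r in screen_catalogue(mirnas))

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_mirnas=5, n_full_match=4, n_partial_match=4)


class TestGenome:
    def test_zero_m6a_probability_yields_no_modified_targets(self):
        cfg = SimulationConfig(
            rng_seed=2, n_genes=60, n_mirnas=5, n_full_match=1, n_partial_match=0,
            p_m6a_given_target=0.0, p_m6a_given_nontarget=0.0,
            p_geneset_only=0.0, p_motif_only=0.0,
        )
        res = simulate_all(cfg)
        assert not any(t.m6a_modified_target for t in res.gene_truth.values())
        assert res.m6a_gene_set == set()

    def test_strict_mode_genome_equalizes_rules(self):
        cfg = SimulationConfig(
            rng_seed=4, n_genes=60, n_mirnas=5, n_full_match=1, n_partial_match=0,
            motif_in_site=True, p_geneset_only=0.0, p_motif_only=0.0,
        )
        res = simulate_all(cfg)
        for t in res.gene_truth.values():
            assert t.m6a_modified_target == t.m6a_modified_target_strict

    def test_peaks_match_planted_motif_intervals(self, small_simulation):
        res = small_simulation
        by_gene = {g: t for g, t in res.gene_truth.items()}
        for gene, start, end in res.peaks:
            t = by_gene[gene]
            assert (t.motif_start, t.motif_end) == (start, end)
            motif_text = next(u for u in res.utrs if u.gene_id == gene).sequence.residues[start:end]
            assert scan_motif(NucleotideSequence("m", motif_text), GGACH)


class TestScoresAndTimecourse:
    def test_score_group_shift_matches_config(self, small_simulation):
        res = small_simulation
        cfg = res.config
        mod = [res.scores[g] for g, t in res.gene_truth.items()
               if t.is_target and t.m6a_modified_target]
        unmod = [res.scores[g] for g, t in res.gene_truth.items()
                 if t.is_target and not t.m6a_modified_target]
        assert set(res.scores) == {g for g, t in res.gene_truth.items() if t.is_target}
        # group means sit near their configured centers (3 se tolerance)
        for vals, mu in ((mod, cfg.score_mean_base + cfg.score_delta_m6a),
                        (unmod, cfg.score_mean_base)):
            se = cfg.score_sd / np.sqrt(len(vals))
            assert abs(np.mean(vals) - mu) < 3 * se + 1e-9

    def test_small_fold_change_gives_all_unchanged(self):
        from m6amir import call_regulation, CALL_UNCHANGED

        cfg = SimulationConfig(rng_seed=5, n_genes=40, n_mirnas=5, n_full_match=1,
                               n_partial_match=0, fold_change_magnitude=1.2)
        res = simulate_all(cfg)
        calls = call_regulation(res.matrix, "S1", fc_threshold=1.5)
        assert all(c.call == CALL_UNCHANGED for c in calls)

    def test_all_down_exercises_infinite_ratio(self):
        from m6amir import call_regulation, summarize_ratios
        import math

        cfg = SimulationConfig(rng_seed=6, n_genes=40, n_mirnas=5, n_full_match=1,
                               n_partial_match=0, f_down_m6a=1.0, f_down_non_m6a=1.0)
        res = simulate_all(cfg)
        calls = call_regulation(res.matrix, "S1")
        s, _, fold = summarize_ratios(calls, calls, {})
        assert not s.ratio_defined and math.isinf(s.down_up_ratio)
        assert math.isnan(fold)

    def test_multi_stage_truth_per_stage(self):
        cfg = SimulationConfig(rng_seed=8, n_genes=30, n_mirnas=5, n_full_match=1,
                               n_partial_match=0, n_stages=4)
        res = simulate_all(cfg)
        assert set(res.regulation_truth) == {"S1", "S2", "S3"}
        from m6amir import call_regulation

        for stage, planted in res.regulation_truth.items():
            calls = call_regulation(res.matrix, stage)
            assert all(c.call == planted[c.gene_id] for c in calls)


class TestDeterminism:
    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(rng_seed=9, n_genes=40, n_mirnas=10,
                               n_full_match=1, n_partial_match=2)
        p1 = write_simulation(simulate_all(cfg), tmp_path / "a")
        p2 = write_simulation(simulate_all(cfg), tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self, tmp_path):
        c1 = SimulationConfig(rng_seed=1, n_genes=20, n_mirnas=5, n_full_match=0,
                              n_partial_match=0)
        c2 = SimulationConfig(rng_seed=2, n_genes=20, n_mirnas=5, n_full_match=0,
                              n_partial_match=0)
        r1, r2 = simulate_all(c1), simulate_all(c2)
        assert [u.sequence.residues for u in r1.utrs] != [
            u.sequence.residues for u in r2.utrs
        ]
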