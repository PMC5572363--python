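"""Inflation factor, order collinearity, and the resampling experiments."""

import numpy as np
import pandas as pd
import pytest

from cosegmap import (
    ExperimentDesign,
    GeneticMap,
    inflation_factor,
    order_collinearity,
    phase1_sequential,
    phase2_sampled,
    records_to_frame,
    summarize,
)
from cosegmap.expansion import _round_half_up


class TestInflationFactor:
    def test_equal_lengths_zero(self):
        assert inflation_factor(2052.0, 2052.0) == 0.0

    def test_genome_wide_arithmetic(self):
        # full map 2421.1 cM vs skeleton 2052.0 cM
        assert inflation_factor(2421.1, 2052.0) == pytest.approx(17.99, abs=0.005)

    def test_single_lg_arithmetic(self):
        assert inflation_factor(154.4, 137.3) == pytest.approx(12.45, abs=0.005)

    def test_scale_invariance(self):
        base = inflation_factor(120.0, 100.0)
        for c in (0.1, 3.0, 1e4):
            assert inflation_factor(120.0 * c, 100.0 * c) == pytest.approx(base)

    def test_negative_allowed_zero_skeleton_rejected(self):
        assert inflation_factor(90.0, 100.0) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            inflation_factor(100.0, 0.0)


class TestOrderCollinearity:
    def _maps(self, order_a, order_b):
        a = GeneticMap("LG1", list(order_a), np.arange(len(order_a), dtype=float) * 0)
        b = GeneticMap("LG1", list(order_b), np.arange(len(order_b), dtype=float) * 0)
        return a, b

    def test_identical_orders(self):
        a, b = self._maps("abcdefghij", "abcdefghij")
        assert order_collinearity(a, b) == pytest.approx(1.0)

    def test_reversed_order_scores_one(self):
        a, b = self._maps("abcdefghij", "jihgfedcba")
        assert order_collinearity(a, b) == pytest.approx(1.0)

    def test_adjacent_swap(self):
        # one adjacent swap in 10: rho = 1 - 6*2/(10*99) = 0.98787...
        a, b = self._maps("abcdefghij", "bacdefghij")
        assert order_collinearity(a, b) == pytest.approx(1 - 12 / 990, abs=1e-9)
        assert order_collinearity(a, b) == pytest.approx(0.9879, abs=1e-4)

    def test_extra_markers_ignored(self):
        seq = GeneticMap("LG1", list("axbycz"), np.zeros(6))
        sket = GeneticMap("LG1", list("abc"), np.zeros(3))
        assert order_collinearity(seq, sket) == pytest.approx(1.0)

    def test_too_few_shared_markers(self):
        a, b = self._maps("ab", "ab")
        with pytest.raises(ValueError):
            order_collinearity(a, b)


class TestPhase1Sequential:
    def test_record_count_equals_n_coseg(self, clean_lg_experiment):
        matrix, cs, smap = clean_lg_experiment
        records = phase1_sequential(matrix, cs, smap, fn="haldane", seed=3)
        assert len(records) == cs.n_coseg
        ks = [r.markers_added for r in records]
        assert ks == list(range(1, cs.n_coseg + 1))

    def test_zero_noise_gives_zero_inflation(self, clean_lg_experiment):
        matrix, cs, smap = clean_lg_experiment
        df = records_to_frame(phase1_sequential(matrix, cs, smap, fn="haldane", seed=3))
        assert (df["IF"] == 0.0).all()
        assert (df["spearman_rho"] == 1.0).all()

    def test_no_coseg_markers_empty(self):
        from conftest import matrix_from_strings
        from cosegmap import build_skeleton, find_clusters

        m = matrix_from_strings(
            {"a": "AB" * 15, "b": "AABB" * 7 + "AB", "c": "BA" * 15}
        )
        cs = find_clusters(m, list(m.markers), rng=0, min_informative=20)
        smap = build_skeleton(m, cs)
        assert phase1_sequential(m, cs, smap, seed=1) == []

    def test_seed_reproducible(self, clean_lg_experiment):
        matrix, cs, smap = clean_lg_experiment
        a = records_to_frame(phase1_sequential(matrix, cs, smap, seed=5))
        b = records_to_frame(phase1_sequential(matrix, cs, smap, seed=5))
        pd.testing.assert_frame_equal(a, b)


class TestPhase2Sampled:
    def test_round_half_up_rule(self):
        assert _round_half_up(0.10 * 290) == 29
        assert _round_half_up(0.15 * 290) == 44  # 43.5 rounds up
        assert _round_half_up(2.5) == 3

    def test_bookkeeping_full_design(self, noisy_lg_experiment):
        matrix, cs, smap = noisy_lg_experiment
        design = ExperimentDesign(replicates=2, fallback_replicates=2, master_seed=9)
        records = phase2_sampled(matrix, cs, smap, design, fn="haldane")
        available = 100 * cs.n_coseg / cs.n_markers
        levels, reps = design.for_lg(available)
        assert len(records) == len(levels) * reps
        for r in records:
            expected = _round_half_up(r.proportion_pct / 100 * cs.n_coseg)
            assert r.markers_added == expected
            assert r.IF == pytest.approx(
                (r.L_seq - r.L_sket) / r.L_sket * 100, abs=1e-12
            )

    def test_fallback_design_for_low_coseg_lg(self):
        design = ExperimentDesign()
        levels, reps = design.for_lg(68.0)
        assert levels == (10, 20, 30, 40, 50, 60)
        assert reps == 20
        full_levels, full_reps = design.for_lg(85.0)
        assert full_levels == (10, 20, 30, 40, 50, 60, 70, 80)
        assert full_reps == 50

    def test_single_record_reproducible_in_isolation(self, noisy_lg_experiment):
        matrix, cs, smap = noisy_lg_experiment
        full = phase2_sampled(
            matrix, cs, smap,
            ExperimentDesign(replicates=2, fallback_replicates=2, master_seed=4),
            fn="haldane",
        )
        one_level = phase2_sampled(
            matrix, cs, smap,
            ExperimentDesign(levels=(30,), fallback_levels=(30,), replicates=2,
                             fallback_replicates=2, master_seed=4),
            fn="haldane",
        )
        target = [r for r in full if r.proportion_pct == 30.0 and r.replicate == 1][0]
        alone = [r for r in one_level if r.replicate == 1][0]
        assert alone.L_seq == target.L_seq
        assert alone.IF == target.IF

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(levels=(20, 10))
        with pytest.raises(ValueError):
            ExperimentDesign(replicates=0)
        with pytest.raises(ValueError):
            ExperimentDesign(levels=(0, 10))


class TestSummarize:
    def _frame(self, ifs, level=10.0):
        rows = [
            {"lg_id": "LG01", "mode": "phaseII_sampled", "proportion_pct": level,
             "markers_added": 3, "replicate": i, "L_seq": 100 + v, "L_sket": 100.0,
             "IF": v, "spearman_rho": 1.0}
            for i, v in enumerate(ifs)
        ]
        return pd.DataFrame(rows)

    def test_all_zero(self):
        out = summarize(self._frame([0.0, 0.0, 0.0]))
        row = out["by_level"].iloc[0]
        assert row["mean_IF"] == 0.0 and row["sd_IF"] == 0.0 and row["n_maps"] == 3

    def test_mean_and_sample_sd(self):
        out = summarize(self._frame([10.0, 20.0]))
        row = out["by_level"].iloc[0]
        assert row["mean_IF"] == pytest.approx(15.0)
        assert row["sd_IF"] == pytest.approx(7.0711, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())
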