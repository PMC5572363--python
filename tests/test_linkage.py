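"""Recombination estimation, mapping functions, grouping, ordering, assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest, spearmanr

from cosegmap import (
    GeneticMap,
    SimConfig,
    build_map,
    correct_double_recombinants,
    estimate_r,
    group_markers,
    inverse_map_distance,
    map_distance,
    order_markers,
    pairwise_linkage_matrix,
    simulate_dh_population,
)
from cosegmap.linkage import sarf

from conftest import matrix_from_strings


class TestEstimateR:
    def test_identical_columns(self):
        m = matrix_from_strings({"a": "AB" * 5, "b": "AB" * 5})
        pl = estimate_r(m, "a", "b", min_informative=10)
        assert pl.r_hat == 0.0
        assert pl.n_discordant == 0
        assert pl.n_informative == 10

    def test_direct_count(self):
        m = matrix_from_strings({"a": "AAAAABBBBB", "b": "AAAAABBBBA"})
        pl = estimate_r(m, "a", "b", min_informative=10)
        assert pl.r_hat == pytest.approx(0.1)

    def test_half_discordant_p_is_one(self):
        m = matrix_from_strings({"a": "AAAAABBBBB", "b": "BBBBBBBBBB"})
        pl = estimate_r(m, "a", "b", min_informative=10)
        assert pl.r_hat == 0.5
        assert pl.p_indep == pytest.approx(1.0)

    def test_missing_excluded_and_uninformative_flagged(self):
        m = matrix_from_strings({"a": "ABABABAB" + "UU", "b": "UUABABAB" + "AB"})
        pl = estimate_r(m, "a", "b", min_informative=20)
        assert pl.n_informative == 6
        assert not pl.informative
        assert pl.p_indep == 1.0

    @pytest.mark.parametrize("k,n", [(0, 20), (3, 20), (10, 20), (17, 31), (25, 50)])
    def test_p_value_matches_exact_binomial_test(self, k, n):
        # oracle: scipy's exact two-sided binomial test at p=1/2
        calls_a = "A" * n
        calls_b = "B" * k + "A" * (n - k)
        m = matrix_from_strings({"a": calls_a, "b": calls_b})
        pl = estimate_r(m, "a", "b", min_informative=n)
        expected = binomtest(k, n, 0.5).pvalue
        assert pl.p_indep == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_self(self):
        m = matrix_from_strings({"a": "ABBABABA" * 4, "b": "AABBABBA" * 4})
        ab = estimate_r(m, "a", "b", min_informative=10)
        ba = estimate_r(m, "b", "a", min_informative=10)
        assert ab.r_hat == ba.r_hat
        assert estimate_r(m, "a", "a").r_hat == 0.0


class TestMapDistance:
    def test_zero(self):
        assert map_distance(0.0, "haldane") == 0.0
        assert map_distance(0.0, "kosambi") == 0.0

    def test_reference_values(self):
        assert map_distance(0.1, "haldane") == pytest.approx(-50 * np.log(0.8))
        assert map_distance(0.1, "haldane") == pytest.approx(11.157, abs=5e-4)
        assert map_distance(0.1, "kosambi") == pytest.approx(25 * np.log(1.5))
        assert map_distance(0.1, "kosambi") == pytest.approx(10.137, abs=5e-4)

    @pytest.mark.parametrize("bad", [-0.01, 0.5, 0.6])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            map_distance(bad, "haldane")

    @settings(derandomize=True, max_examples=200)
    @given(r=st.floats(min_value=0.0, max_value=0.4999))
    def test_roundtrip_and_function_inequality(self, r):
        for fn in ("haldane", "kosambi"):
            assert inverse_map_distance(map_distance(r, fn), fn) == pytest.approx(
                r, abs=1e-9
            )
        dk, dh = map_distance(r, "kosambi"), map_distance(r, "haldane")
        assert dk <= dh + 1e-12
        if r > 1e-6:  # below this the two functions agree to float precision
            assert dk < dh

    @settings(derandomize=True, max_examples=100)
    @given(
        r1=st.floats(min_value=0.0, max_value=0.49),
        r2=st.floats(min_value=0.0, max_value=0.49),
    )
    def test_strictly_increasing(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        for fn in ("haldane", "kosambi"):
            assert map_distance(lo, fn) < map_distance(hi, fn)


class TestGrouping:
    def test_two_chromosomes_two_groups(self):
        pos = np.arange(21) * 5.0
        cfg = SimConfig(
            n_lines=200, n_lg=2, lg_length_cM=100.0, locus_positions=[pos, pos],
            coseg_proportion=0.0, seed=4,
        )
        matrix, truth = simulate_dh_population(cfg)
        groups, unplaced = group_markers(matrix)
        assert len(groups) == 2
        assert not unplaced
        for g in groups:
            assert truth.table.loc[g, "lg_id"].nunique() == 1

    def test_identical_columns_one_group(self):
        m = matrix_from_strings({f"m{i}": "AB" * 20 for i in range(4)})
        groups, unplaced = group_markers(m)
        assert len(groups) == 1 and sorted(groups[0]) == [f"m{i}" for i in range(4)]

    def test_marker_without_informative_overlap_unplaced(self):
        base = "AB" * 20
        rows = {"a": base, "b": base}
        # marker c observed only where a and b are missing
        rows["c"] = "U" * 38 + "AB"
        rows["a"] = base[:38] + "UU"
        rows["b"] = base[:38] + "UU"
        m = matrix_from_strings(rows)
        groups, unplaced = group_markers(m)
        assert "c" in unplaced


class TestOrdering:
    def test_two_markers_canonical_orientation(self):
        m = matrix_from_strings({"z": "AB" * 15, "a": "BA" * 15})
        assert order_markers(m, ["z", "a"]) == ["a", "z"]

    @pytest.mark.parametrize("seed", range(25))
    def test_sarf_matches_bruteforce_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        m_loci = int(rng.integers(4, 8))
        cfg = SimConfig(
            n_lines=int(rng.integers(150, 260)), n_lg=1,
            lg_length_cM=float(rng.uniform(40, 120)), n_unique_loci=m_loci,
            coseg_proportion=0.0, miscall_rate=0.01, missing_rate=0.02,
            seed=int(rng.integers(2**31)),
        )
        matrix, _ = simulate_dh_population(cfg)
        order = order_markers(matrix, list(matrix.markers))
        r, _, _, _ = pairwise_linkage_matrix(matrix, list(matrix.markers))
        w = np.nan_to_num(r, nan=0.5)
        np.fill_diagonal(w, 0.0)
        idx = {mk: i for i, mk in enumerate(matrix.markers)}
        got = sarf([idx[x] for x in order], w)
        best = min(
            sarf(p, w) for p in itertools.permutations(range(matrix.n_markers))
        )
        assert got == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_true_order_error_free(self, seed):
        # 50 loci spaced 5 cM apart, no noise: the returned order must be
        # the true order up to reversal, or an order the sampled
        # recombinants cannot distinguish from it (equal SARF)
        pos = np.arange(50) * 5.0
        cfg = SimConfig(
            n_lines=200, n_lg=1, lg_length_cM=245.0, locus_positions=[pos],
            coseg_proportion=0.0, seed=100 + seed,
        )
        matrix, truth = simulate_dh_population(cfg)
        order = order_markers(matrix, list(matrix.markers))
        tp = truth.table.loc[order, "true_position_cM"].to_numpy()
        exact = bool(np.all(np.diff(tp) > 0) or np.all(np.diff(tp) < 0))
        if not exact:
            r, _, _, _ = pairwise_linkage_matrix(matrix, list(matrix.markers))
            w = np.nan_to_num(r, nan=0.5)
            np.fill_diagonal(w, 0.0)
            idx = {mk: i for i, mk in enumerate(matrix.markers)}
            true_order = list(
                np.argsort(truth.table.loc[matrix.markers, "true_position_cM"])
            )
            assert sarf([idx[x] for x in order], w) <= sarf(true_order, w) + 1e-12
            assert abs(spearmanr(tp, np.arange(len(tp))).statistic) > 0.999

    def test_deterministic(self, noisy_lg):
        _, matrix, _ = noisy_lg
        group = list(matrix.markers)[:30]
        assert order_markers(matrix, group) == order_markers(matrix, group)


class TestBuildMap:
    def test_zero_length_for_identical_markers(self):
        m = matrix_from_strings({f"m{i}": "AB" * 15 for i in range(4)})
        gmap = build_map(m, [f"m{i}" for i in range(4)], fn="haldane")
        assert gmap.length == 0.0
        assert np.all(gmap.positions == 0.0)

    def test_cumulative_haldane_positions(self):
        # adjacent r of 0.1 twice: length = 2 * 11.157 = 22.314 cM
        a = "AAAAAAAAAABBBBBBBBBB"
        b = "AAAAAAAABBBBBBBBBBBB"  # differs at lines 9,10 -> r = 0.1
        c = "AAAAAABBBBBBBBBBBBBB"  # differs from b at lines 7,8 -> r = 0.1
        m = matrix_from_strings({"a": a, "b": b, "c": c})
        gmap = build_map(m, ["a", "b", "c"], fn="haldane")
        assert gmap.positions[0] == 0.0
        assert gmap.length == pytest.approx(2 * -50 * np.log(0.8), abs=1e-9)
        assert gmap.length == pytest.approx(22.314, abs=1e-3)

    def test_uninformative_adjacent_pair_raises_with_names(self):
        m = matrix_from_strings({"a": "AB" * 10 + "UU", "b": "UU" * 10 + "AB"})
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            build_map(m, ["a", "b"])

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap("LG1", ["a", "b"], np.array([1.0, 2.0]))  # must start at 0
        with pytest.raises(ValueError):
            GeneticMap("LG1", ["a", "b"], np.array([0.0, -1.0]))


class TestDoubleRecombinantCorrection:
    def _map(self, markers, positions):
        return GeneticMap("LG1", markers, np.asarray(positions, dtype=float))

    def test_textbook_double_recombinant_corrected(self):
        m = matrix_from_strings({"a": "A", "b": "B", "c": "A"})
        gmap = self._map(["a", "b", "c"], [0.0, 1.0, 2.0])
        fixed, log = correct_double_recombinants(m, gmap)
        assert fixed.column("b")[0] == 0  # now A
        assert len(log) == 1
        assert log.iloc[0]["old"] == "B" and log.iloc[0]["new"] == "A"

    def test_single_crossover_untouched(self):
        m = matrix_from_strings({"a": "A", "b": "B", "c": "B"})
        gmap = self._map(["a", "b", "c"], [0.0, 1.0, 2.0])
        fixed, log = correct_double_recombinants(m, gmap)
        assert len(log) == 0
        assert fixed == m

    def test_terminal_markers_and_missing_never_modified(self):
        m = matrix_from_strings({"a": "B", "b": "A", "c": "U", "d": "A", "e": "B"})
        gmap = self._map(["a", "b", "c", "d", "e"], [0.0, 1.0, 2.0, 3.0, 4.0])
        fixed, log = correct_double_recombinants(m, gmap)
        assert fixed.column("c")[0] == -1  # missing not imputed
        assert fixed.column("a")[0] == 1 and fixed.column("e")[0] == 1

    def test_window_limits_flank_search(self):
        m = matrix_from_strings({"a": "A", "b": "B", "c": "A"})
        gmap = self._map(["a", "b", "c"], [0.0, 20.0, 40.0])
        fixed, log = correct_double_recombinants(m, gmap, window_cM=10.0)
        assert len(log) == 0  # flanks outside the window

    def test_correction_shrinks_noisy_map(self, noisy_lg):
        _, matrix, _ = noisy_lg
        order = order_markers(matrix, list(matrix.markers))
        before = build_map(matrix, order, fn="haldane")
        fixed, log = correct_double_recombinants(matrix, before)
        after = build_map(fixed, order, fn="haldane")
        assert len(log) > 0
        assert after.length < before.length
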