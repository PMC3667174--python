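"""Two-point estimation, grouping, COUNT ordering and map assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rilmap as rm
from rilmap.linkage_map import (add_totals_row, build_groups, collapse_loci,
                                count_of_order, find_gaps, haldane_cm,
                                haldane_waddington_R, haldane_waddington_r,
                                kosambi_cm, map_statistics, order_group,
                                pairwise_two_point, position_loci,
                                summarize_map, two_point)


def _matrix(rows: dict[str, str]) -> pd.DataFrame:
    data = {m: list(codes) for m, codes in rows.items()}
    n = len(next(iter(data.values())))
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=[f"r{i}" for i in range(n)])


def _random_matrix(rng, n_markers, n_samples, missing=0.05):
    codes = rng.choice(["A", "B"], size=(n_markers, n_samples))
    mask = rng.random((n_markers, n_samples)) < missing
    codes[mask] = "-"
    return pd.DataFrame(codes, index=[f"m{i:02d}" for i in range(n_markers)],
                        columns=[f"r{i}" for i in range(n_samples)])


class TestTwoPoint:
    def test_identical_vectors_closed_form(self):
        row = "AB" * 47
        m = _matrix({"m1": row, "m2": row})
        est = two_point(m, ("m1", "m2"))
        assert est.n_informative == 94 and est.n_recombinant == 0
        assert est.r_hat == 0.0 and est.r == 0.0
        assert est.lod == pytest.approx(94 * math.log10(2), abs=1e-9)
        assert round(est.lod, 2) == 28.30

    def test_free_recombination_fixed_point(self):
        m = _matrix({"m1": "A" * 10 + "B" * 10,
                     "m2": "B" * 5 + "A" * 5 + "A" * 5 + "B" * 5})
        est = two_point(m, ("m1", "m2"))
        assert est.r_hat == 0.5 and est.r == 0.5 and est.lod == 0.0

    def test_h_codes_are_uninformative(self):
        m = _matrix({"m1": "AABB" + "H" * 6, "m2": "AABB" + "A" * 6})
        est = two_point(m, ("m1", "m2"), min_informative=4)
        assert est.n_informative == 4

    def test_too_few_informative_marked(self):
        m = _matrix({"m1": "AB", "m2": "AB"})
        est = two_point(m, ("m1", "m2"))
        assert math.isnan(est.r_hat) and est.lod == 0.0

    def test_pairwise_agrees_with_single(self):
        rng = np.random.default_rng(50)
        m = _random_matrix(rng, 8, 40)
        tables = pairwise_two_point(m, min_informative=10)
        for i, j in itertools.combinations(range(8), 2):
            est = two_point(m, (m.index[i], m.index[j]))
            assert tables.k[i, j] == est.n_recombinant
            assert tables.n[i, j] == est.n_informative
            assert tables.lod[i, j] == pytest.approx(est.lod, abs=1e-9)

    def test_simulated_pair_recovers_true_r(self):
        # true r = 0.10 between two loci over 2000 RILs
        rng = np.random.default_rng(51)
        n = 2000
        R_true = haldane_waddington_R(0.10)
        g1 = rng.choice(["A", "B"], size=n)
        flip = rng.random(n) < R_true
        g2 = np.where(flip, np.where(g1 == "A", "B", "A"), g1)
        m = pd.DataFrame([g1, g2], index=["m1", "m2"])
        est = two_point(m, ("m1", "m2"))
        se = math.sqrt(R_true * (1 - R_true) / n)
        assert abs(est.r_hat - R_true) < 3 * se
        assert abs(est.r - 0.10) < 0.02


class TestHaldaneWaddington:
    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.5))
    def test_round_trip_to_ten_digits(self, r):
        R = haldane_waddington_R(r)
        assert haldane_waddington_r(R) == pytest.approx(r, abs=1e-10, rel=1e-10)

    def test_correction_monotone_and_bounded(self):
        grid = np.linspace(0.0, 0.499, 200)
        vals = [haldane_waddington_r(R) for R in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(R / 2 <= v <= R for R, v in zip(grid, vals))


class TestMappingFunctions:
    def test_zero_r_zero_distance(self):
        assert haldane_cm(0.0) == 0.0 and kosambi_cm(0.0) == 0.0

    def test_closed_form_values_at_r01(self):
        assert round(haldane_cm(0.1), 3) == 11.157
        assert round(kosambi_cm(0.1), 3) == 10.137


class TestGrouping:
    def test_two_unlinked_clusters_stay_separate(self):
        rng = np.random.default_rng(52)
        n = 60
        base1 = rng.choice(["A", "B"], size=n)
        base2 = rng.choice(["A", "B"], size=n)
        rows = {}
        for i in range(3):
            rows[f"x{i}"] = "".join(base1)
            rows[f"y{i}"] = "".join(base2)
        m = _matrix(rows)
        tables = pairwise_two_point(m)
        groups, trace = build_groups(tables, target_groups=2)
        assert len(groups) == 2
        assert {frozenset(g) for g in groups} == {
            frozenset(["x0", "x1", "x2"]), frozenset(["y0", "y1", "y2"])}

    def test_unlinked_singleton_remains_alone(self):
        rng = np.random.default_rng(53)
        n = 60
        base = "".join(rng.choice(["A", "B"], size=n))
        lone = "".join(rng.choice(["A", "B"], size=n))
        m = _matrix({"a1": base, "a2": base, "lone": lone})
        tables = pairwise_two_point(m)
        groups, _ = build_groups(tables, target_groups=2)
        assert ["lone"] in groups

    def test_simulated_chromosomes_group_purely(self, recovery):
        lmap = recovery["lmap"]
        truth = recovery["truth_pos"]
        assert len(lmap.groups) == 5
        for g in lmap.groups:
            chroms = {truth[m][0] for l in g.loci for m in l.markers}
            assert len(chroms) == 1


class TestOrdering:
    def test_two_marker_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(54)
        m = _random_matrix(rng, 2, 30)
        tables = pairwise_two_point(m)
        order, _ = order_group(tables, ["m01", "m00"])
        assert order[0] == "m00"

    def test_reversal_leaves_count_unchanged(self):
        rng = np.random.default_rng(55)
        m = _random_matrix(rng, 6, 40)
        tables = pairwise_two_point(m)
        idx = list(range(6))
        assert (count_of_order(idx, tables.k)
                == count_of_order(idx[::-1], tables.k))

    @pytest.mark.parametrize("trial", range(30))
    def test_small_instances_attain_bruteforce_minimum(self, trial):
        rng = np.random.default_rng(560 + trial)
        n_markers = int(rng.integers(3, 8))
        m = _random_matrix(rng, n_markers, 20, missing=0.2)
        tables = pairwise_two_point(m, min_informative=1)
        _, count = order_group(tables, list(m.index), seed=trial)
        best = min(count_of_order(list(p), tables.k)
                   for p in itertools.permutations(range(n_markers)))
        assert count == best

    def test_simulated_group_order_matches_truth(self, recovery):
        from scipy.stats import kendalltau
        truth = recovery["truth_pos"]
        for g in recovery["lmap"].groups:
            markers = [m for l in g.loci for m in l.markers]
            pos = [truth[m][1] for m in markers]
            tau = abs(kendalltau(pos, range(len(pos))).statistic)
            assert tau >= 0.95


class TestLociAndPositions:
    def test_mutual_zero_recombinants_single_locus(self):
        row = "AB" * 20
        m = _matrix({"m1": row, "m2": row, "m3": row})
        tables = pairwise_two_point(m)
        assert collapse_loci(["m1", "m2", "m3"], tables) == [["m1", "m2", "m3"]]

    def test_no_zero_pairs_no_collapse(self, recovery):
        rng = np.random.default_rng(57)
        m = _random_matrix(rng, 5, 60, missing=0.0)
        tables = pairwise_two_point(m)
        order = list(m.index)
        if all(tables.k[tables.index(a), tables.index(b)] > 0
               for a, b in zip(order, order[1:])):
            assert len(collapse_loci(order, tables)) == 5

    def test_zero_r_zero_position(self):
        row = "AB" * 20
        m = _matrix({"m1": row, "m2": row})
        tables = pairwise_two_point(m)
        positions, flags = position_loci([["m1"], ["m2"]], tables)
        assert positions == [0.0, 0.0] and not flags

    def test_unlinked_adjacency_capped_and_flagged(self):
        m = _matrix({"m1": "A" * 10 + "B" * 10,
                     "m2": "B" * 5 + "A" * 5 + "A" * 5 + "B" * 5})
        tables = pairwise_two_point(m)
        positions, flags = position_loci([["m1"], ["m2"]], tables)
        assert positions[1] == 50.0 and flags

    def test_simulated_length_recovery(self, recovery):
        got = recovery["lmap"].total_length_cm
        truth = recovery["truth_length_cm"]
        assert abs(got - truth) / truth < 0.15


class TestGapsAndSummary:
    def _toy_map(self, spacings):
        loci = []
        pos = 0.0
        for i, d in enumerate([0.0] + spacings):
            pos += d
            loci.append(rm.Locus(f"m{i}", pos, [f"m{i}"]))
        return rm.LinkageGroupMap([rm.LinkageGroup("SLG-1", loci)])

    def test_uniform_spacing_no_gaps(self):
        assert find_gaps(self._toy_map([1.0] * 30)).empty

    def test_single_wide_interval_detected(self):
        gaps = find_gaps(self._toy_map([1.0, 25.0, 1.0]))
        assert len(gaps) == 1 and gaps.iloc[0]["gap_cm"] == 25.0

    def test_empty_map_zero_totals(self):
        summary = summarize_map(rm.LinkageGroupMap([]))
        stats = map_statistics(summary)
        assert stats["total_markers"] == 0 and stats["total_length_cm"] == 0.0

    def test_totals_row_is_exact_sum(self):
        df = pd.DataFrame({"group": ["g1", "g2"], "n_markers": [10, 20],
                           "n_loci": [2, 3], "length_cm": [10.5, 20.0]})
        out = add_totals_row(df)
        total = out[out["group"] == "Total"].iloc[0]
        assert total["n_markers"] == 30 and total["length_cm"] == 30.5

    def test_published_group_table_statistics(self):
        summary = rm.published_map_summary()
        stats = map_statistics(summary)
        assert stats["total_markers"] == 8246
        assert stats["total_loci"] == 1517
        assert stats["total_length_cm"] == 1629.9
        assert stats["total_scaffolds"] == 4214
        assert stats["total_scaffold_span_bp"] == 71_751_603
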