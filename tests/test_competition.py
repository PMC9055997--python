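import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crownforge.competition import (
    CompetitionConfig,
    InsufficientNeighborsError,
    compute_plot_indices,
    find_competitors_fixed_number,
    find_competitors_fixed_radius,
    hegyi_index,
    hegyi_per_tree,
    pairwise_distance,
    plot_competition_index,
)
from crownforge.stem_map import DominantRule

from conftest import make_stand, random_stand


def record(sm, i):
    return list(sm.records())[i]


class TestPairwiseDistance:
    def test_euclidean_345(self):
        assert pairwise_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_torus_wraps_short_way(self):
        d = pairwise_distance((1, 1), (119, 1), geometry="torus", stand_dims=(120, 140))
        assert d == pytest.approx(2.0)

    def test_euclidean_does_not_wrap(self):
        assert pairwise_distance((1, 1), (119, 1)) == pytest.approx(118.0)


class TestFixedRadius:
    def test_neighbor_inside_radius_found(self):
        sm = make_stand([60, 60], [70, 74.9], [10, 12])
        comps = find_competitors_fixed_radius(record(sm, 0), sm)
        assert len(comps) == 1
        assert comps[0][1] == pytest.approx(4.9)

    def test_boundary_distance_included(self):
        sm = make_stand([60, 60], [70, 75.0], [10, 12])
        comps = find_competitors_fixed_radius(record(sm, 0), sm)
        assert len(comps) == 1  # radius boundary is closed

    def test_isolated_subject_empty(self):
        sm = make_stand([10, 60], [10, 70], [10, 12])
        assert find_competitors_fixed_radius(record(sm, 0), sm) == []


class TestFixedNumber:
    def test_one_candidate_per_quadrant(self):
        sm = make_stand([60, 63, 57, 57, 63], [70, 73, 73, 67, 67], [10, 12, 14, 16, 18])
        comps = find_competitors_fixed_number(record(sm, 0), sm)
        assert sorted(c.tree_id for c, _ in comps) == ["t0001", "t0002", "t0003", "t0004"]

    def test_empty_quadrant_filled_by_next_nearest(self):
        # quadrant I holds trees at 1 m and 2 m, II and III one each, IV none:
        # expect the 1 m tree, the II and III trees, and the 2 m tree as fill
        sm = make_stand(
            [60, 60.8, 61.2, 59, 59], [70, 70.6, 71.6, 71, 69], [10, 12, 14, 16, 18]
        )
        comps = find_competitors_fixed_number(record(sm, 0), sm)
        ids = {c.tree_id for c, _ in comps}
        assert ids == {"t0001", "t0002", "t0003", "t0004"}

    def test_equidistant_ties_resolved_by_id(self):
        sm = make_stand([60, 62, 62, 62, 58], [70, 70.0, 70.0, 70.0, 70.0], [10, 12, 14, 16, 18])
        first = find_competitors_fixed_number(record(sm, 0), sm)
        second = find_competitors_fixed_number(record(sm, 0), sm)
        assert [c.tree_id for c, _ in first] == [c.tree_id for c, _ in second]
        # coincident candidates in one quadrant: the smallest id wins the slot
        assert first[0][0].tree_id == "t0001"

    def test_too_few_trees_raises(self):
        sm = make_stand([60, 62], [70, 70], [10, 12])
        with pytest.raises(InsufficientNeighborsError):
            find_competitors_fixed_number(record(sm, 0), sm)


class TestHegyiIndex:
    def test_single_competitor(self):
        sm = make_stand([60, 64], [70, 70], [10, 20])
        comps = [(record(sm, 1), 4.0)]
        assert hegyi_index(record(sm, 0), comps) == pytest.approx(0.4)

    def test_two_competitors_with_zero_distance(self):
        sm = make_stand([60, 60, 64], [70, 70, 70], [10, 10, 5])
        comps = [(record(sm, 1), 0.0), (record(sm, 2), 4.0)]
        assert hegyi_index(record(sm, 0), comps) == pytest.approx(1.1)

    def test_empty_set_is_zero(self):
        sm = make_stand([60], [70], [10])
        assert hegyi_index(record(sm, 0), []) == 0.0


class TestPlotIndices:
    def setup_method(self):
        self.sm = make_stand([5, 10, 15], [5, 10, 15], [10, 20, 30])
        self.plot = self.sm.df

    def test_sum_of_dbh(self):
        assert plot_competition_index(self.plot, self.sm, "SD") == pytest.approx(60.0)

    def test_relative_dbh_uses_mean_dominant(self):
        v = plot_competition_index(
            self.plot, self.sm, "SRD", dominant_rule=DominantRule(count=None)
        )
        assert v == pytest.approx(3.0)  # MDD = 20, 60/20

    def test_basal_area_single_tree(self):
        sm = make_stand([5], [5], [20.0])
        assert plot_competition_index(sm.df, sm, "SBA") == pytest.approx(np.pi * 0.01)

    def test_unknown_index_rejected(self):
        from crownforge.stem_map import ConfigurationError

        with pytest.raises(ConfigurationError):
            plot_competition_index(self.plot, self.sm, "XXX")

    def test_table_covers_all_plots_and_indices(self, small_stand):
        table = compute_plot_indices(small_stand)
        assert set(table.columns) >= {"SD", "SDD", "SRD", "SBA", "SHGN", "SHGR", "MDD"}
        assert sorted(table["plot_id"]) == small_stand.plot_ids()
        assert (table[["SD", "SDD", "SRD", "SBA", "SHGN", "SHGR"]] >= 0).all().all()


def brute_force_shgr(sm, radius=5.0):
    """All-pairs double loop oracle for the fixed-radius Hegyi index."""
    df = sm.df
    n = len(df)
    x, y, d = df["x"].to_numpy(), df["y"].to_numpy(), df["dbh"].to_numpy()
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = pairwise_distance(
                (x[i], y[i]), (x[j], y[j]), geometry="torus",
                stand_dims=(sm.stand_width, sm.stand_height),
            )
            if L <= radius:
                out[i] += d[j] / (d[i] * (L + 1.0))
    return out


class TestEdgeCorrectionProperties:
    def test_neighbor_search_matches_bruteforce_small(self, rng):
        sm = random_stand(rng, n=40)
        fast = hegyi_per_tree(sm, rule="fixed_radius")
        assert np.allclose(fast, brute_force_shgr(sm), atol=1e-10)

    def test_tiling_equals_torus_for_small_radius(self, rng):
        sm = random_stand(rng, n=80)
        torus = hegyi_per_tree(sm, rule="fixed_radius", config=CompetitionConfig(edge_correction="torus"))
        tiled = hegyi_per_tree(sm, rule="fixed_radius", config=CompetitionConfig(edge_correction="tiling"))
        assert np.allclose(torus, tiled, atol=1e-10)

    def test_translation_invariance_on_torus(self, rng):
        sm = random_stand(rng, n=60)
        shifted = make_stand(
            np.mod(sm.df["x"] + 37.0, 120.0), np.mod(sm.df["y"] + 53.0, 140.0),
            sm.df["dbh"],
        )
        a = hegyi_per_tree(sm, rule="fixed_radius")
        b = hegyi_per_tree(shifted, rule="fixed_radius")
        assert np.allclose(a, b, atol=1e-9)

    def test_dbh_scale_invariance_and_scaling(self, rng):
        sm = random_stand(rng, n=50)
        scaled = make_stand(sm.df["x"], sm.df["y"], 3.0 * sm.df["dbh"])
        t1 = compute_plot_indices(sm)
        t2 = compute_plot_indices(scaled)
        merged = t1.merge(t2, on="plot_id", suffixes=("_a", "_b"))
        assert np.allclose(merged["SRD_a"], merged["SRD_b"])
        assert np.allclose(merged["SHGN_a"], merged["SHGN_b"])
        assert np.allclose(merged["SHGR_a"], merged["SHGR_b"])
        assert np.allclose(3.0 * merged["SD_a"], merged["SD_b"])
        assert np.allclose(3.0 * merged["SDD_a"], merged["SDD_b"])
        assert np.allclose(9.0 * merged["SBA_a"], merged["SBA_b"])

    @given(
        dj=st.floats(min_value=1.0, max_value=40.0),
        bump=st.floats(min_value=0.0, max_value=10.0),
        closer=st.floats(min_value=0.0, max_value=3.0),
    )
    @settings(deadline=None, max_examples=30)
    def test_hegyi_monotone_in_size_and_proximity(self, dj, bump, closer):
        sm = make_stand([60, 64], [70, 70], [10.0, dj])
        subj = record(sm, 0)
        base = hegyi_index(subj, [(record(sm, 1), 4.0)])
        bigger = make_stand([60, 64], [70, 70], [10.0, dj + bump])
        assert hegyi_index(subj, [(record(bigger, 1), 4.0)]) >= base
        assert hegyi_index(subj, [(record(sm, 1), 4.0 - closer)]) >= base
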