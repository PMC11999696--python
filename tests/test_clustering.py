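import numpy as np
import pandas as pd
import pytest

from pcmorph import synth
from pcmorph.clustering import (
    ShuffleSpec, adjacency_scores, cluster_runs, clustering_excess,
    count_rates, demographics, interhemisphere_difference, match_labels,
    population_match_profile, population_match_rates, shell_match_profile,
    shuffle_labels, shuffle_map,
)

from conftest import make_map, random_map
from oracles import oracle_population_rates, oracle_runs, oracle_scores


class TestAdjacencyScores:
    def test_isolated_cells_keep_initial_minus_one(self):
        df = make_map(["V-Split", "V-Split"], spacing=5000.0)  # beyond 1000 µm
        out = adjacency_scores(df)
        assert list(out["score"]) == [-1, -1]

    def test_three_identical_adjacent_cells_score_1_2_1(self):
        df = make_map(["V-Split"] * 3, spacing=100.0)
        assert list(adjacency_scores(df)["score"]) == [1, 2, 1]

    def test_mouse_n_s_s_p_sequence_scores_0_1_1_0(self):
        df = make_map(["Normative", "V-Split", "V-Split", "V-Poly"],
                      spacing=100.0, species="mouse")
        assert list(adjacency_scores(df)["score"]) == [0, 1, 1, 0]

    def test_match_modes_differ_on_partial_matches(self):
        # V-Split next to H-Split: no complete match, but a type_only match
        df = make_map(["V-Split", "H-Split"], spacing=100.0)
        assert list(adjacency_scores(df, match_mode="complete")["score"]) == [0, 0]
        assert list(adjacency_scores(df, match_mode="type_only")["score"]) == [1, 1]
        assert list(adjacency_scores(df, match_mode="orientation_only")["score"]) == [0, 0]

    def test_species_default_thresholds(self):
        # 500 µm gaps: within the human 1000 µm threshold, beyond mouse 200 µm
        human = make_map(["V-Poly"] * 3, spacing=500.0, species="human")
        mouse = make_map(["V-Poly"] * 3, spacing=500.0, species="mouse")
        assert list(adjacency_scores(human)["score"]) == [1, 2, 1]
        assert list(adjacency_scores(mouse)["score"]) == [-1, -1, -1]


class TestRuns:
    def test_single_run_of_three_cells_200um(self):
        df = make_map(["V-Split"] * 3, spacing=100.0)
        runs = cluster_runs(adjacency_scores(df))
        assert len(runs) == 1
        assert runs.loc[0, "n_cells"] == 3
        assert runs.loc[0, "run_length_um"] == pytest.approx(200.0)

    def test_no_matches_no_runs(self):
        df = make_map(["Normative", "V-Split", "H-Poly"], spacing=100.0)
        assert len(cluster_runs(adjacency_scores(df))) == 0

    def test_alternating_categories_no_runs_in_complete_mode(self):
        df = make_map(["V-Split", "H-Split"] * 5, spacing=100.0)
        assert len(cluster_runs(adjacency_scores(df))) == 0

    def test_subthreshold_gap_terminates_run(self):
        df = make_map(["V-Split"] * 4, x=[0.0, 100.0, 5000.0, 5100.0])
        runs = cluster_runs(adjacency_scores(df))
        assert len(runs) == 2
        assert list(runs["n_cells"]) == [2, 2]


class TestShuffles:
    def test_label_multiset_conserved_globally(self, rng):
        df = random_map(rng, 200)
        for shuf in shuffle_map(df, ShuffleSpec(n_reps=5, seed=9)):
            assert sorted(match_labels(shuf)) == sorted(match_labels(df))
            assert np.array_equal(shuf["x"], df["x"])
            assert list(shuf["foliar"]) == list(df["foliar"])

    def test_per_stratum_multisets_conserved_within_foliar(self, rng):
        df = random_map(rng, 200)
        shuf = shuffle_map(df, ShuffleSpec("within_foliar", n_reps=1, seed=4))[0]
        for stratum in ("Gyrus", "Bank", "Sulcus"):
            a = sorted(match_labels(df[df["foliar"] == stratum]))
            b = sorted(match_labels(shuf[shuf["foliar"] == stratum]))
            assert a == b

    def test_same_seed_same_permutation(self, rng):
        df = random_map(rng, 100)
        a = shuffle_map(df, ShuffleSpec(n_reps=3, seed=7))
        b = shuffle_map(df, ShuffleSpec(n_reps=3, seed=7))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestBruteForceEquivalence:
    def test_scores_and_runs_match_oracle_on_random_maps(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 31))
            df = random_map(rng, n)
            for mode in ("complete", "type_only", "orientation_only"):
                out = adjacency_scores(df, 150.0, mode)
                assert list(out["score"]) == oracle_scores(df, 150.0, mode)
                got = [(r.n_cells, pytest.approx(r.run_length_um))
                       for r in cluster_runs(out).itertuples()]
                assert got == [(c, pytest.approx(l))
                               for c, l in oracle_runs(df, 150.0, mode)]

    def test_population_rates_match_oracle(self, rng):
        for _ in range(10):
            df = random_map(rng, int(rng.integers(5, 31)))
            rates = population_match_rates(df, 400.0)
            expected = oracle_population_rates(df, 400.0)
            for row in rates.itertuples():
                if row.category in expected:
                    assert row.match_rate == pytest.approx(expected[row.category])
                else:
                    assert np.isnan(row.match_rate)


class TestClusteringExcess:
    def test_identical_labels_give_zero_excess(self):
        df = make_map(["V-Poly"] * 50, spacing=100.0)
        assert clustering_excess(df, ShuffleSpec(n_reps=5, seed=1)) == pytest.approx(0.0)

    def test_all_isolated_is_flagged(self):
        df = make_map(["V-Poly"] * 5, spacing=9000.0)
        with pytest.raises(ValueError, match="isolated"):
            clustering_excess(df, ShuffleSpec(n_reps=5, seed=1))

    def test_copying_strength_raises_excess_monotonically(self):
        # averaged over replicate maps, the excess must rank exactly with the
        # generative copy probability
        kappas = [0.0, 0.4, 0.8]
        means = []
        for k in kappas:
            vals = []
            for rep in range(8):
                cfg = synth.human_map_config(
                    300, seed=1000 + rep, copy_probability=k)
                cmap, _ = synth.simulate_cell_map(cfg)
                vals.append(clustering_excess(
                    cmap, ShuffleSpec(n_reps=10, seed=rep)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[2] > 20.0  # strong copying is far from the null


class TestProfiles:
    def test_alternating_map_has_depressed_matching_at_one_neighbor_radius(self):
        df = make_map(["V-Split", "H-Poly"] * 10, spacing=100.0)
        prof = population_match_profile(
            df, [120.0], ShuffleSpec(n_reps=200, seed=3))
        # observed matching rate is 0; shuffled ≈ 50% -> elevation ≈ −50
        assert prof.matching[0] == pytest.approx(-50.0, abs=4.0)
        assert prof.nonmatching[0] == pytest.approx(+50.0, abs=4.0)

    def test_single_category_map_has_zero_elevation(self):
        df = make_map(["V-Poly"] * 30, spacing=100.0)
        prof = population_match_profile(df, [300.0], ShuffleSpec(n_reps=5, seed=2))
        assert prof.matching[0] == pytest.approx(0.0)

    def test_independent_labels_have_near_zero_elevation(self, rng):
        cfg = synth.human_map_config(400, seed=17, copy_probability=0.0)
        cmap, _ = synth.simulate_cell_map(cfg)
        prof = population_match_profile(
            cmap, [1000.0], ShuffleSpec(n_reps=40, seed=5))
        assert abs(prof.matching[0]) < 3.0

    def test_match_plus_nonmatch_elevations_cancel(self, rng):
        df = random_map(rng, 60)
        prof = population_match_profile(
            df, [200.0, 500.0], ShuffleSpec(n_reps=10, seed=6))
        pc = prof.per_category
        assert np.allclose(pc["match_elevation"] + pc["nonmatch_elevation"], 0.0)

    def test_shells_tile_the_line_disjointly(self, rng):
        df = random_map(rng, 50)
        prof = shell_match_profile(df, 500.0, 4, ShuffleSpec(n_reps=5, seed=8))
        assert np.allclose(prof.inner_radii, [0, 500, 1000, 1500])
        assert np.allclose(prof.radii, [500, 1000, 1500, 2000])

    def test_short_range_copying_fades_beyond_first_shells(self):
        # copying acts between immediate neighbours (~100 µm apart in mouse),
        # so elevation should be concentrated at short range and ≈ 0 far out
        cfg = synth.mouse_map_config(600, seed=23, copy_probability=0.6)
        cmap, _ = synth.simulate_cell_map(cfg)
        prof = shell_match_profile(cmap, 100.0, 8, ShuffleSpec(n_reps=20, seed=3))
        assert prof.matching[0] > 10.0
        assert abs(np.mean(prof.matching[-3:])) < 4.0


class TestDemographics:
    def test_identical_groups_give_null_chi_squared(self):
        df = make_map(["V-Split"] * 20 + ["H-Poly"] * 20,
                      lobule=(["L5"] * 10 + ["L6"] * 10) * 2)
        pct, chi2, p, dof = demographics(df)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_percentages_per_group(self):
        df = make_map(["V-Split"] * 3 + ["H-Poly"],
                      lobule=["L5", "L5", "L5", "L6"])
        with pytest.raises(ValueError):
            demographics(df[df["lobule"] == "L5"])  # single group
        pct, *_ = demographics(df)
        assert pct.loc["L5", "V-Split"] == pytest.approx(100.0)
        assert pct.loc["L6", "H-Poly"] == pytest.approx(100.0)

    def test_innervation_count_tabulation(self):
        counts = {"putative_mono": 22, "absence": 11,
                  "putative_multi": 6, "fully_labeled_multi": 5}
        rates = count_rates(counts)
        assert rates["putative_mono"] == pytest.approx(50.0)
        assert rates["absence"] == pytest.approx(25.0)
        assert rates["putative_multi"] == pytest.approx(100 * 6 / 44, abs=0.05)
        assert rates["fully_labeled_multi"] == pytest.approx(100 * 5 / 44, abs=0.05)
        # putative + fully labeled multi-innervation: at least a quarter
        assert rates["putative_multi"] + rates["fully_labeled_multi"] == pytest.approx(25.0)


class TestInterhemisphere:
    def _map(self, labels, hemisphere, lobule):
        return make_map(labels, hemisphere=hemisphere,
                        lobule=[lobule] * len(labels))

    def test_identical_hemispheres_give_zero_and_flag_normalization(self):
        left = pd.concat([self._map(["V-Split"] * 10, "left", "L5"),
                          self._map(["H-Poly"] * 10, "left", "L6")])
        right = left.assign(hemisphere="right")
        out = interhemisphere_difference(left, right)
        assert np.allclose(out["mean_abs_diff_pct"], 0.0)
        assert not out["normalizable"].any()
        assert out["normalized_to_reference"].isna().all()

    def test_swapping_hemispheres_leaves_values_unchanged(self, rng):
        left = pd.concat([
            make_map([("V-Split", "H-Poly")[i] for i in rng.integers(0, 2, 30)],
                     lobule=["L5"] * 30),
            make_map([("V-Split", "V-Poly")[i] for i in rng.integers(0, 2, 30)],
                     lobule=["L6"] * 30),
        ])
        right = pd.concat([
            make_map([("V-Split", "H-Poly")[i] for i in rng.integers(0, 2, 30)],
                     lobule=["L5"] * 30),
            make_map([("Normative", "V-Poly")[i] for i in rng.integers(0, 2, 30)],
                     lobule=["L6"] * 30),
        ])
        a = interhemisphere_difference(left, right)
        b = interhemisphere_difference(right, left)
        pd.testing.assert_frame_equal(a, b)

    def test_normalization_is_ratio_to_reference_lobule(self):
        # L5 differs by 40 points on two classes; L6 by 20 points on two
        left = pd.concat([self._map(["V-Split"] * 5 + ["H-Poly"] * 5, "left", "L5"),
                          self._map(["V-Split"] * 5 + ["H-Poly"] * 5, "left", "L6")])
        right = pd.concat([
            self._map(["V-Split"] * 7 + ["H-Poly"] * 3, "right", "L5"),
            self._map(["V-Split"] * 6 + ["H-Poly"] * 4, "right", "L6"),
        ])
        out = interhemisphere_difference(left, right).set_index("lobule")
        # L5: |50−70| and |50−30| on two classes, 0 elsewhere -> mean 8
        assert out.loc["L5", "mean_abs_diff_pct"] == pytest.approx(8.0)
        assert out.loc["L6", "mean_abs_diff_pct"] == pytest.approx(4.0)
        assert out.loc["L5", "normalized_to_reference"] == pytest.approx(2.0)

    def test_missing_reference_lobule_rejected(self):
        left = self._map(["V-Split"] * 5, "left", "L5")
        right = self._map(["V-Split"] * 5, "right", "L5")
        with pytest.raises(ValueError, match="L6"):
            interhemisphere_difference(left, right)
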