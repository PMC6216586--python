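"""Trajectory likelihood-ratio scoring and the neighbor-support filter."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_track, oracle_null_loglik, oracle_score, toy_marker_map
from poolage.core import TrajectoryTable
from poolage.scoring import (
    NeighborOutlierFilter,
    TrajectoryScorer,
    combine_replicates,
    neighbor_filter,
    null_loglik,
    saturated_loglik,
    score_trajectory,
)


class TestNullModel:
    def test_pooled_mle_is_total_fraction(self):
        p_hat, _ = null_loglik([2, 10, 18], [20, 20, 20])
        assert p_hat == pytest.approx(30 / 60)

    def test_boundary_all_zero_counts_give_certain_fit(self):
        p_hat, logl = null_loglik([0, 0], [20, 20])
        assert p_hat == 0.0
        assert logl == 0.0

    def test_all_depths_zero_is_signalled(self):
        with pytest.raises(ValueError):
            null_loglik([0, 0], [0, 0])

    def test_zero_depth_timepoints_contribute_nothing(self):
        p1, l1 = null_loglik([2, 10, 0], [20, 20, 0])
        p2, l2 = null_loglik([2, 10], [20, 20])
        assert p1 == p2 and l1 == l2

    def test_mle_matches_grid_search_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(0, 200, size=6)
            k = rng.binomial(n, rng.uniform(0, 1))
            if not (n > 0).any():
                continue
            p_hat, _ = null_loglik(k, n)
            p_grid, _ = oracle_null_loglik(k, n)
            assert p_hat == pytest.approx(p_grid, abs=1e-4)


class TestSaturatedModel:
    def test_constant_frequency_definition(self):
        from scipy.stats import binom

        assert saturated_loglik([10, 10, 10], [20, 20, 20]) == pytest.approx(
            3 * binom.logpmf(10, 20, 0.5)
        )

    def test_boundary_frequencies_have_zero_logpmf(self):
        assert saturated_loglik([0, 20], [20, 20]) == 0.0

    def test_saturated_nests_null(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 100, size=4)
            k = rng.binomial(n, rng.uniform(0, 1))
            _, l0 = null_loglik(k, n)
            assert saturated_loglik(k, n) >= l0 - 1e-9


class TestTrajectoryScore:
    def test_constant_trajectory_scores_zero(self):
        assert score_trajectory([10, 10, 10], [20, 20, 20]) == 0.0

    def test_worked_example(self):
        # frozen via the brute-force oracle; p_hat=0.5 vs (0.1, 0.5, 0.9)
        s = score_trajectory([2, 10, 18], [20, 20, 20])
        assert s == pytest.approx(14.722568286739884, abs=1e-9)
        assert s == pytest.approx(oracle_score([2, 10, 18], [20, 20, 20]), abs=1e-6)

    def test_timepoint_permutation_invariance(self, rng):
        k, n = [2, 10, 18, 5], [20, 20, 20, 30]
        base = score_trajectory(k, n)
        perm = rng.permutation(4)
        assert score_trajectory(np.array(k)[perm], np.array(n)[perm]) == pytest.approx(base)

    def test_single_informative_timepoint_is_undefined(self):
        assert np.isnan(score_trajectory([5], [10]))
        assert np.isnan(score_trajectory([5, 0], [10, 0]))


class TestCombineReplicates:
    def test_sum_of_defined_scores(self):
        s, n = combine_replicates([1.0, 2.0, 3.0])
        assert (s, n) == (6.0, 3)

    def test_missing_replicate_skipped_with_count(self):
        s, n = combine_replicates([1.0, np.nan, 3.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        assert s == pytest.approx(10.0)
        assert n == 7

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            combine_replicates([np.nan, np.nan])

    def test_null_combined_score_respects_chi2_limit(self, rng):
        """At high depth under no change, 2S is ~chi2 with sum_r (T_r - 1) df."""
        from scipy.stats import chi2

        R, T, depth = 8, 6, 5000
        df = R * (T - 1)
        stats = []
        for _ in range(500):
            n = np.full((R, T), depth)
            k = rng.binomial(n, 0.5)
            s = sum(score_trajectory(k[r], n[r]) for r in range(R))
            stats.append(2 * s)
        stats = np.asarray(stats)
        # stochastic dominance probe: no heavier tail than the chi2 limit
        q95 = chi2.ppf(0.95, df)
        assert (stats > q95).mean() <= 0.08
        assert np.median(stats) <= chi2.ppf(0.5, df) * 1.1


class TestTableScorer:
    def test_matches_scalar_path_and_sums_replicates(self, rng):
        markers = toy_marker_map(4)
        k = rng.integers(0, 10, size=(4, 3, 5))
        n = k + rng.integers(0, 10, size=(4, 3, 5))
        table = TrajectoryTable(markers, k, n)
        scorer = TrajectoryScorer().fit(table)
        for m in range(4):
            per_rep = [score_trajectory(k[m, r], n[m, r]) for r in range(3)]
            expected, cnt = combine_replicates(per_rep)
            assert scorer.scores_["score"].iloc[m] == pytest.approx(expected, abs=1e-9)
            assert scorer.scores_["n_replicates"].iloc[m] == cnt

    def test_replicate_permutation_leaves_combined_score(self, rng):
        markers = toy_marker_map(3)
        n = rng.integers(1, 50, size=(3, 4, 6))
        k = rng.binomial(n, 0.4)
        base = TrajectoryScorer().fit(TrajectoryTable(markers, k, n)).scores_["score"]
        perm = rng.permutation(4)
        shuf = TrajectoryScorer().fit(TrajectoryTable(markers, k[:, perm], n[:, perm])).scores_["score"]
        assert np.allclose(base, shuf)

    def test_sklearn_params_roundtrip(self):
        scorer = TrajectoryScorer(min_depth=5)
        assert scorer.get_params()["min_depth"] == 5
        scorer.set_params(min_depth=2)
        assert scorer.min_depth == 2


class TestNeighborFilter:
    def test_isolated_spike_is_filtered(self):
        track = make_track([2, 3, 2, 3, 50, 3, 2, 3, 2])
        out = neighbor_filter(track)
        # IQR of the scores is 1 under linear-interpolation quantiles
        assert NeighborOutlierFilter().fit(track).iqr_ == pytest.approx(1.0)
        assert list(out["filtered"]) == [False] * 4 + [True] + [False] * 4

    def test_adjacent_spikes_support_each_other(self):
        track = make_track([2, 3, 50, 49, 3, 2])
        out = neighbor_filter(track)
        assert not out["filtered"].to_numpy()[2:4].any()

    def test_constant_track_untouched(self):
        out = neighbor_filter(make_track([5.0] * 10))
        assert not out["filtered"].any()

    def test_either_rule_is_stricter(self):
        track = make_track([2, 3, 50, 49, 3, 2])
        strict = neighbor_filter(track, rule="either")
        assert strict["filtered"].to_numpy()[2:4].all()

    def test_terminal_locus_uses_single_neighbor(self):
        track = make_track([50, 3, 2, 3, 2, 3, 2, 3])
        out = neighbor_filter(track)
        assert bool(out["filtered"].iloc[0])

    def test_chromosome_boundaries_respected(self):
        a = make_track([2, 3, 2, 3, 2], chrom="I")
        b = make_track([50, 3, 2, 3, 2], chrom="II")
        out = neighbor_filter(pd.concat([a, b], ignore_index=True))
        # the 50 heads chromosome II: compared only to its one neighbor there
        assert bool(out["filtered"].iloc[5])
        assert not out["filtered"].iloc[:5].any()


class TestScoreOracleBattery:
    def test_thousand_random_trajectories_match_bruteforce(self, rng):
        """Vectorized scorer vs independent lgamma/grid oracle, <=1e-6."""
        markers = toy_marker_map(1000)
        n = rng.integers(0, 201, size=(1000, 1, 6))
        p = rng.uniform(0, 1, size=(1000, 1, 1))
        k = rng.binomial(n, p)
        table = TrajectoryTable(markers, k, n)
        scores = TrajectoryScorer().fit(table).scores_["score"].to_numpy()
        check = rng.choice(1000, size=60, replace=False)  # oracle is slow; spot-check
        for m in check:
            if (n[m, 0] > 0).sum() < 2:
                assert np.isnan(scores[m])
            else:
                assert scores[m] == pytest.approx(oracle_score(k[m, 0], n[m, 0]), abs=1e-6)
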