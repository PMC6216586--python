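"""Forward simulator: meiosis, selection, aging, and read sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from poolage.core import DEFAULT_CHROMOSOMES
from poolage.simulate import (
    CausalLocus,
    SegregantPool,
    SelectionModel,
    SequencingModel,
    SimConfig,
    age_pool,
    build_marker_map,
    founder_pool,
    grow,
    intercross,
    meiosis_batch,
    sample_reads,
    simulate_experiment,
)


@pytest.fixture(scope="module")
def one_morgan_map():
    # single chromosome whose genetic length is exactly 1 Morgan
    df = pd.DataFrame(
        {
            "chrom": "I",
            "pos": np.linspace(1, 200_000, 50).astype(int),
            "short_allele": "A",
            "long_allele": "G",
            "kind": "SNP",
        }
    )
    from poolage.core import MarkerMap

    return MarkerMap(df, chrom_lengths={"I": 200_000}, cm_per_kb=0.5)


class TestMeiosis:
    def test_expected_crossovers_equal_map_length(self, one_morgan_map, rng):
        pool = founder_pool(one_morgan_map, 2)
        pa = np.zeros(4000, dtype=int)
        pb = np.ones(4000, dtype=int)
        _, xo = meiosis_batch(pool, pa, pb, one_morgan_map, rng, return_crossovers=True)
        # Poisson with mean = 1 Morgan; MC error ~ 1/sqrt(4000)
        assert xo.mean() == pytest.approx(1.0, abs=3 / np.sqrt(4000))

    def test_offspring_alleles_come_from_parents(self, one_morgan_map, rng):
        pool = founder_pool(one_morgan_map, 2)
        off = meiosis_batch(pool, np.zeros(10, int), np.ones(10, int), one_morgan_map, rng)
        assert off.dtype == bool and off.shape == (10, 50)
        # mosaic of an all-0 and an all-1 parent: both alleles appear overall
        assert 0 < off.mean() < 1


class TestIntercross:
    def test_neutral_allele_frequency_stays_half(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers)
        afs = []
        for seed in range(200):
            pool = founder_pool(one_morgan_map, 50)
            out = intercross(pool, 2, 50, model, one_morgan_map, seed)
            afs.append(out.allele_frequency().mean())
        afs = np.asarray(afs)
        se = afs.std(ddof=1) / np.sqrt(len(afs))
        assert abs(afs.mean() - 0.5) < 3 * se + 1e-12

    def test_growth_selection_matches_deterministic_recursion(self, one_morgan_map):
        """Single-locus haploid selection: p' = p e^g / (p e^g + 1 - p)."""
        g_eff, gens = 0.5, 10
        j = 25
        growth = np.zeros(one_morgan_map.n_markers)
        growth[j] = g_eff
        model = SelectionModel(one_morgan_map.n_markers, growth=growth)
        p = 0.5
        for _ in range(gens):
            p = p * np.exp(g_eff) / (p * np.exp(g_eff) + 1 - p)
        finals = []
        for seed in range(30):
            pool = founder_pool(one_morgan_map, 1000)
            out = intercross(pool, gens, 1000, model, one_morgan_map, seed)
            finals.append(out.allele_frequency()[j])
        finals = np.asarray(finals)
        assert finals.mean() > 0.5
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - p) < 4 * se + 0.02

    def test_selected_frequency_increases_with_generations(self, one_morgan_map):
        growth = np.zeros(one_morgan_map.n_markers)
        growth[10] = 0.5
        model = SelectionModel(one_morgan_map.n_markers, growth=growth)
        afs = []
        for gens in (1, 5, 10):
            vals = [
                intercross(founder_pool(one_morgan_map, 500), gens, 500, model,
                           one_morgan_map, seed).allele_frequency()[10]
                for seed in range(10)
            ]
            afs.append(np.mean(vals))
        assert afs[0] < afs[1] < afs[2]

    def test_errors(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers)
        with pytest.raises(ValueError):
            intercross(SegregantPool(np.zeros((1, 50), bool)), 1, 10, model, one_morgan_map, 0)
        with pytest.raises(ValueError):
            intercross(founder_pool(one_morgan_map, 4), -1, 10, model, one_morgan_map, 0)

    def test_deterministic_given_seed(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers)
        a = intercross(founder_pool(one_morgan_map, 20), 3, 20, model, one_morgan_map, 7)
        b = intercross(founder_pool(one_morgan_map, 20), 3, 20, model, one_morgan_map, 7)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestAging:
    def test_uniform_mortality_halves_viability_and_keeps_af(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers, beta0=0.0)  # 50%/day
        vias, dafs = [], []
        for seed in range(100):
            pool = founder_pool(one_morgan_map, 400)
            res = age_pool(pool, model, days=3, rng=seed)
            vias.append(res.viability[3])
            if res.survivors[3] > 0:
                dafs.append(res.af[3].mean() - res.af[0].mean())
        assert np.mean(vias) == pytest.approx(0.5**3, abs=0.01)
        assert abs(np.mean(dafs)) < 3 * np.std(dafs, ddof=1) / np.sqrt(len(dafs)) + 1e-12

    def test_survival_selection_matches_two_class_recursion(self, one_morgan_map):
        """p_{d+1} = p_d s1 / (p_d s1 + (1-p_d) s0), s_i the daily survivals."""
        j, s_eff, days = 25, 2.0, 4
        surv = np.zeros(one_morgan_map.n_markers)
        surv[j] = s_eff
        model = SelectionModel(one_morgan_map.n_markers, survival=surv, beta0=0.0)
        s1, s0 = expit(s_eff), expit(0.0)
        expected = [0.5]
        for _ in range(days):
            p = expected[-1]
            expected.append(p * s1 / (p * s1 + (1 - p) * s0))
        traj = np.full((60, days + 1), np.nan)
        for seed in range(60):
            pool = founder_pool(one_morgan_map, 2000)
            traj[seed] = age_pool(pool, model, days=days, rng=seed).af[:, j]
        mean_traj = np.nanmean(traj, axis=0)
        assert np.all(np.diff(mean_traj) > 0)  # monotone enrichment
        se = np.nanstd(traj, axis=0, ddof=1) / np.sqrt(60)
        assert np.all(np.abs(mean_traj - expected) < 4 * se + 0.01)

    def test_extinct_pool_flags_af_missing(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers, beta0=-20.0)  # ~certain death
        res = age_pool(founder_pool(one_morgan_map, 10), model, days=2, rng=0)
        assert res.survivors[-1] == 0
        assert np.isnan(res.af[-1]).all()
        assert res.viability[-1] == 0.0

    def test_survivors_non_increasing(self, one_morgan_map):
        model = SelectionModel(one_morgan_map.n_markers)
        res = age_pool(founder_pool(one_morgan_map, 300), model, days=6, rng=1)
        assert np.all(np.diff(res.survivors) <= 0)


class TestGrow:
    def test_growth_selection_purges_deleterious_allele(self, one_morgan_map):
        growth = np.zeros(one_morgan_map.n_markers)
        growth[5] = -0.5
        model = SelectionModel(one_morgan_map.n_markers, growth=growth)
        pool = founder_pool(one_morgan_map, 2000)
        out = grow(pool, model, rounds=8, rng=3)
        assert out.allele_frequency()[5] < 0.3

    def test_empty_pool_raises(self, one_morgan_map):
        pool = founder_pool(one_morgan_map, 10)
        pool.alive[:] = False
        with pytest.raises(ValueError):
            grow(pool, SelectionModel(one_morgan_map.n_markers), 1, 0)


class TestSequencing:
    def test_extreme_frequencies_are_exact(self, rng):
        seq = SequencingModel(mean_depth=30)
        k, n = sample_reads(np.zeros(100), seq, rng)
        assert (k == 0).all()
        k, n = sample_reads(np.ones(100), seq, rng)
        assert np.array_equal(k, n)

    def test_counts_within_binomial_error(self, rng):
        seq = SequencingModel(mean_depth=100)
        k, n = sample_reads(np.full(10_000, 0.5), seq, rng)
        assert ((k >= 0) & (k <= n)).all()
        frac = k[n > 0] / n[n > 0]
        assert 0.49 < frac.mean() < 0.51

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            SequencingModel(mean_depth=0)
        with pytest.raises(ValueError):
            sample_reads(np.array([1.5]), SequencingModel(10), rng)

    def test_nan_frequency_yields_missing_observation(self, rng):
        k, n = sample_reads(np.array([np.nan, 0.5]), SequencingModel(50), rng)
        assert (k[0], n[0]) == (0, 0)


class TestExperimentGeneration:
    def test_shapes_and_conservation(self):
        config = SimConfig(n_markers=60, pool_size=50, replicates=8, timepoints=6,
                           mean_depth=20)
        exp = simulate_experiment(config, seed=11)
        assert exp.table.shape == (exp.markers.n_markers, 8, 6)
        assert (exp.table.k <= exp.table.n).all()
        assert len(exp.curves) == 8
        assert exp.markers.n_markers >= 2 * len(DEFAULT_CHROMOSOMES)

    def test_reproducible_bit_identical(self):
        config = SimConfig(n_markers=40, pool_size=30, replicates=2, timepoints=3,
                           mean_depth=10)
        a = simulate_experiment(config, seed=5)
        b = simulate_experiment(config, seed=5)
        assert np.array_equal(a.table.k, b.table.k)
        assert np.array_equal(a.table.n, b.table.n)
        assert a.markers.df.equals(b.markers.df)

    def test_truth_table_records_causal_position(self):
        config = SimConfig(n_markers=50, pool_size=40, replicates=1, timepoints=3,
                           mean_depth=10, causal=[CausalLocus(s=1.0, g=-0.2)])
        exp = simulate_experiment(config, seed=2)
        assert len(exp.truth) == 1
        idx = int(exp.truth["marker_index"].iloc[0])
        assert exp.truth["pos"].iloc[0] == exp.markers.df["pos"].iloc[idx]
        assert exp.model.survival[idx] == 1.0

    def test_bad_config_dimensions_raise(self):
        with pytest.raises(ValueError):
            SimConfig(replicates=0)
        with pytest.raises(ValueError):
            SimConfig(timepoints=1)
        with pytest.raises(KeyError):
            SimConfig.from_dict({"not_a_key": 3})
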