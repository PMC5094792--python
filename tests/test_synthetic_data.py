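"""Wright-Fisher simulator, competition/fluctuation/coverage generators."""

import numpy as np
import pytest
from scipy import stats

from gutevo.fluctuation_analysis import lea_coulson_pmf
from gutevo.genome_analysis import call_cnv, gc_normalize, mutation_spectrum
from gutevo.muller_reconstruction import Haplotype
from gutevo.synthetic_data import (
    LocusSpec,
    PopulationExtinctError,
    SamplingSpec,
    SimulationConfig,
    gaussian_gc_bias,
    sample_lea_coulson,
    simulate_competition,
    simulate_coverage,
    simulate_fluctuation_assay,
    simulate_gut_population,
    synth_mutation_table,
    synthetic_population_series,
)


def quiet_sampling():
    return SamplingSpec(colonies_per_day=300, clones_per_timepoint=0)


class TestGutPopulation:
    def test_neutral_dimorphism_stays_constant(self):
        config = SimulationConfig(
            days=10, loci=[], marker_split=0.3,
            sampling=quiet_sampling(), deterministic=True,
        )
        series, _ = simulate_gut_population(config)
        yfp = series.inclusive_frequency(Haplotype("YFP"))
        assert np.allclose(yfp, 0.3, atol=1e-12)

    def test_deterministic_selection_matches_logistic_closed_form(self):
        s, f0 = 0.08, 0.5
        config = SimulationConfig(
            days=24,
            loci=[LocusSpec("mut", fitness_effect=s, initial_frequency=f0)],
            sampling=quiet_sampling(),
            deterministic=True,
        )
        series, _ = simulate_gut_population(config)
        mutant = [h for h in series.haplotypes if "mut" in h.mutations]
        f = sum(series.inclusive_frequency(h) for h in mutant)
        g = series.generations
        expected = f0 * np.exp(s * g) / (1 - f0 + f0 * np.exp(s * g))
        assert np.abs(f - expected).max() < 1e-12

    def test_frequencies_sum_to_one_and_nesting_holds(self):
        config = SimulationConfig(
            population_size=1e6, days=8,
            loci=[
                LocusSpec("a", mutation_rate=1e-6, fitness_effect=0.08),
                LocusSpec("b", mutation_rate=1e-6, fitness_effect=0.05),
            ],
            rng_seed=5,
        )
        series, typing = simulate_gut_population(config)
        assert np.allclose(series.frequencies.sum(axis=0), 1.0, atol=1e-9)
        series.validate_nesting()
        assert all(t.clones_typed <= 45 for t in typing)

    def test_fixed_seed_reproducible(self):
        config = SimulationConfig(
            population_size=1e6, days=5,
            loci=[LocusSpec("a", mutation_rate=1e-6, fitness_effect=0.08)],
            rng_seed=123,
        )
        s1, t1 = simulate_gut_population(config)
        s2, t2 = simulate_gut_population(config)
        assert np.array_equal(s1.frequencies, s2.frequencies)
        assert [t.counts for t in t1] == [t.counts for t in t2]

    def test_no_silent_nans_and_degenerate_configs_rejected(self):
        # extinction surfaces as PopulationExtinctError, never NaNs;
        # under fixed-N resampling a tiny population still never NaNs
        config = SimulationConfig(
            population_size=10, days=3,
            loci=[LocusSpec("a", mutation_rate=0.01, fitness_effect=0.1)],
            sampling=quiet_sampling(), rng_seed=0,
        )
        series, _ = simulate_gut_population(config)
        assert np.isfinite(series.frequencies).all()
        with pytest.raises(ValueError):
            SimulationConfig(population_size=0.0)
        assert issubclass(PopulationExtinctError, RuntimeError)

    def test_hotspot_establishment_matches_branching_process(self):
        """With hotspot supply N*mu = 100 mutants/generation and s = 0.08,
        a branching-process establishment calculation predicts the mutant
        exceeds 50% by day 24 in essentially every replicate."""
        n_pop, mu, s, t, days = 1e7, 1e-5, 0.08, 18, 24
        # establishment probability per mutant: 1 - q, q = exp(e^s (q-1))
        q = 0.5
        for _ in range(200):
            q = np.exp(np.exp(s) * (q - 1))
        pi = 1 - q
        # deterministic post-establishment sweep time to 50%
        sweep_gens = np.log(2 * s * n_pop) / s
        usable = max(days * t - sweep_gens, 0.0)
        p_win = 1 - np.exp(-n_pop * mu * pi * usable)
        wins = 0
        reps = 20
        for seed in range(reps):
            config = SimulationConfig(
                population_size=n_pop, days=days,
                loci=[LocusSpec("gat", mutation_rate=mu, fitness_effect=s)],
                sampling=quiet_sampling(), rng_seed=seed,
            )
            series, _ = simulate_gut_population(config)
            f = sum(
                series.inclusive_frequency(h)
                for h in series.haplotypes
                if "gat" in h.mutations
            )
            wins += f[-1] > 0.5
        assert abs(wins / reps - p_win) <= 0.15


class TestCompetition:
    def test_null_case_unbiased(self):
        ss = []
        for seed in range(100):
            traj = simulate_competition(
                0.0, days=3, colonies_per_day=300, seed=seed
            )[0]
            r = traj.focal_count / traj.reference_count
            ss.append(np.log(r[-1] / r[0]) / 54)
        ss = np.array(ss)
        assert abs(ss.mean()) < 2 * ss.std(ddof=1) / 10

    def test_noiseless_log_ratio_arithmetic(self):
        traj = simulate_competition(0.08, days=3)[0]
        r = traj.focal_count / traj.reference_count
        assert np.log(r[-1] / r[0]) == pytest.approx(0.08 * 54, rel=1e-12)

    def test_fds_converges_to_fixed_point(self):
        traj = simulate_competition((0.04, -0.52), days=9, start_freq=0.9)[0]
        f = traj.frequency()
        assert (np.diff(f) < 0).all()
        # direct-iteration oracle for the fixed point of delta_f = a + b f
        x = 0.9
        for _ in range(9):
            x = x + 0.04 - 0.52 * x
        assert f[-1] == pytest.approx(x, abs=1e-12)
        assert abs(f[-1] - 0.04 / 0.52) < 0.01

    def test_start_freq_validated(self):
        with pytest.raises(ValueError):
            simulate_competition(0.05, days=3, start_freq=1.0)

    def test_ground_truth_recorded(self):
        traj = simulate_competition(0.07, days=3, seed=1)[0]
        assert traj.meta["s_true"] == 0.07


class TestFluctuation:
    def test_mu_zero_gives_all_zero_counts(self):
        exp = simulate_fluctuation_assay(0.0, nt=1e9, cultures=10, seed=0)
        assert (np.asarray(exp.mutant_counts) == 0).all()

    def test_p0_fraction_matches_exp_minus_m(self):
        m = np.log(2)  # p0 = 0.5
        rng = np.random.default_rng(0)
        counts = sample_lea_coulson(m, 10_000, rng)
        p0_hat = (counts == 0).mean()
        ci = stats.binomtest(int((counts == 0).sum()), 10_000).proportion_ci()
        assert ci.low <= 0.5 <= ci.high
        assert abs(p0_hat - 0.5) < 0.02

    @pytest.mark.parametrize("m", [1.0, 5.0])
    def test_sampler_matches_mss_pmf_by_chi_square(self, m):
        rng = np.random.default_rng(1)
        n = 4000
        counts = sample_lea_coulson(m, n, rng)
        k_max = 200
        pmf = lea_coulson_pmf(m, k_max)
        # bins: 0..9 singletons, 10..k_max lumped, then the tail
        edges = list(range(11)) + [k_max + 1, np.inf]
        expected, observed = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if np.isinf(hi):
                p = 1.0 - pmf.sum()
            else:
                p = pmf[lo:hi].sum()
            expected.append(p * n)
            observed.append(((counts >= lo) & (counts < hi)).sum())
        chi2, p_val = stats.chisquare(observed, expected)
        assert p_val > 0.001

    def test_absurd_m_rejected_with_advice(self):
        with pytest.raises(ValueError, match="dilute|plate"):
            simulate_fluctuation_assay(1e-1, nt=1e9, cultures=10)

    def test_seeded_reproducibility(self):
        a = simulate_fluctuation_assay(1e-8, nt=1e9, cultures=10, seed=9)
        b = simulate_fluctuation_assay(1e-8, nt=1e9, cultures=10, seed=9)
        assert np.array_equal(a.mutant_counts, b.mutant_counts)


class TestCoverage:
    def test_flat_profile_mean_one_and_no_calls(self):
        profile = simulate_coverage(2_000_000, mean_depth=100, seed=0)
        ratios = gc_normalize(profile)
        assert ratios.mean() == pytest.approx(1.0, abs=0.01)
        assert call_cnv(profile, ratios) == []

    def test_duplication_recovered_within_one_window(self):
        region = (500_000, 550_000, 2.0)
        profile = simulate_coverage(
            2_000_000, mean_depth=100, cnv_regions=[region],
            gc_bias=gaussian_gc_bias(), seed=1,
        )
        calls = call_cnv(profile, gc_normalize(profile))
        dups = [c for c in calls if c.kind == "duplication"]
        assert len(dups) == 1
        assert abs(dups[0].start - region[0]) <= 250
        assert abs(dups[0].end - region[1]) <= 250
        assert dups[0].mean_ratio == pytest.approx(2.0, rel=0.1)

    def test_deletion_called_exactly(self):
        region = (750_000, 780_000, 0.0)
        profile = simulate_coverage(
            2_000_000, mean_depth=100, cnv_regions=[region], seed=2
        )
        dels = [c for c in call_cnv(profile, gc_normalize(profile))
                if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].start == region[0]
        assert dels[0].end == region[1]

    def test_partial_window_dropped(self):
        profile = simulate_coverage(1001, window=250, seed=0)
        assert len(profile.start) == 4
        assert profile.end[-1] == 1000

    def test_region_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_coverage(1_000, cnv_regions=[(500, 2_000, 2.0)], seed=0)


class TestMutationTableGenerator:
    def test_zero_mean_gives_empty_table(self):
        table = synth_mutation_table(5, 0.0, {"a": 1.0}, seed=0)
        assert len(table) == 0
        assert mutation_spectrum(table).mean_per_clone == 0.0

    def test_parallel_hit_rate_matches_enumeration(self):
        """Uniform weights over 5 loci, 3 clones: per clone each locus is
        hit with probability 1 - exp(-lambda/5) independently, so the
        expected number of loci hit in >= 2 distinct clones has an exact
        closed form to compare against the empirical mean."""
        lam, loci, clones = 2.0, 5, 3
        q = 1 - np.exp(-lam / loci)
        p_ge2 = sum(
            stats.binom.pmf(k, clones, q) for k in range(2, clones + 1)
        )
        expected = loci * p_ge2
        from gutevo.genome_analysis import parallel_targets

        hits = []
        weights = {f"L{i}": 1.0 for i in range(loci)}
        for seed in range(3000):
            table = synth_mutation_table(clones, lam, weights, seed=seed)
            if len(table) == 0:
                hits.append(0)
                continue
            hits.append(len(parallel_targets(table)))
        mean = np.mean(hits)
        se = np.std(hits, ddof=1) / np.sqrt(len(hits))
        assert abs(mean - expected) < 4 * se + 0.01


class TestSyntheticPopulationSeries:
    def test_radA_sweep_reaches_near_fixation(self):
        series = synthetic_population_series("2.10")
        rad = Haplotype("YFP", frozenset({"radA-dup"}))
        assert series.inclusive_frequency(rad).max() > 0.99

    def test_unknown_population_rejected(self):
        with pytest.raises(ValueError):
            synthetic_population_series("9.9")
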