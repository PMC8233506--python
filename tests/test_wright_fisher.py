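"""Wright-Fisher focal-allele simulation engine."""

import numpy as np
import pytest
from scipy import stats as sps

from contingency_lab import wright_fisher as wf
from contingency_lab.wright_fisher import (
    DFEClass, FixationSummary, ReplicateOutcome, SimConfig,
    WrightFisherSimulation, combined_fs, extrapolate_fluctuating,
    next_generation_counts, run_replicate, substitution_frequency,
    sweep_population_sizes,
)


def small_config(**kw):
    defaults = dict(n_pop=100, u_genome=0.0, mu_focal=1e-4, s_focal=0.05,
                    dfe=(), horizon=100)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_zero_fix_threshold_invalid(self):
        with pytest.raises(ValueError):
            small_config(fix_threshold=0.0)

    def test_mu_focal_range(self):
        with pytest.raises(ValueError):
            small_config(mu_focal=1.0)
        with pytest.raises(ValueError):
            small_config(mu_focal=-0.1)

    def test_dfe_proportions_must_sum_to_one(self):
        bad = (DFEClass(-0.1, 0.5), DFEClass(0.05, 0.4))
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(dfe=bad)

    def test_lethal_effect_rejected(self):
        with pytest.raises(ValueError):
            DFEClass(effect=-1.0, proportion=1.0)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_pop=1)


class TestReplicateDynamics:
    def test_focal_never_arises_without_mutation(self):
        out = run_replicate(small_config(mu_focal=0.0), seed=1)
        assert not out.fixed
        assert out.final_focal_freq == 0.0
        assert out.fix_generation is None

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = small_config(mu_focal=1e-3, u_genome=1e-3,
                           dfe=(DFEClass(-0.05, 0.7), DFEClass(0.03, 0.3)))
        a = run_replicate(cfg, seed=42, checkpoints=(50,))
        b = run_replicate(cfg, seed=42, checkpoints=(50,))
        assert a == b

    def test_population_size_conserved_every_generation(self):
        cfg = small_config(n_pop=137, mu_focal=5e-3, u_genome=0.01,
                           dfe=(DFEClass(-0.1, 0.5), DFEClass(0.05, 0.5)),
                           horizon=60)
        sim = WrightFisherSimulation(cfg, seed=7)
        for _ in range(60):
            sim.step()
            assert sim.counts.sum() == 137

    def test_fixation_recorded_with_generation(self):
        cfg = small_config(n_pop=50, mu_focal=5e-2, s_focal=0.5, horizon=2000)
        out = run_replicate(cfg, seed=3)
        assert out.fixed
        assert out.fix_generation is not None
        assert out.final_focal_freq > cfg.fix_threshold

    def test_neutral_recurrent_mutation_expectation(self):
        # with s = 0 and no background, mean final focal frequency matches
        # the cumulative mutation pressure 1 - (1 - mu)^T
        mu, horizon, reps = 1e-4, 200, 200
        cfg = small_config(n_pop=500, mu_focal=mu, s_focal=0.0, horizon=horizon)
        freqs = [run_replicate(cfg, seed=s).final_focal_freq
                 for s in np.random.SeedSequence(11).spawn(reps)]
        expected = 1.0 - (1.0 - mu) ** horizon
        se = np.std(freqs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(freqs) - expected) < 3 * se + 1e-4

    def test_one_generation_transitions_match_multinomial_law(self):
        # two-class population: the resampled class-2 count is Binomial(n, p2)
        counts = np.array([12, 8])
        fitness = np.array([1.0, 1.1])
        n = 20
        rng = np.random.default_rng(99)
        draws = next_generation_counts(counts, fitness, n, rng, n_draws=100_000)
        emp = np.bincount(draws[:, 1], minlength=n + 1) / draws.shape[0]
        p2 = counts[1] * fitness[1] / (counts * fitness).sum()
        exact = sps.binom.pmf(np.arange(n + 1), n, p2)
        tvd = 0.5 * np.abs(emp - exact).sum()
        assert tvd < 0.01

    def test_deleterious_background_never_slows_focal_vs_beneficial(self):
        # replacing a beneficial background class by a deleterious one removes
        # clonal interference, so focal fixation cannot get slower
        base = dict(n_pop=2000, mu_focal=2e-4, s_focal=0.0831,
                    u_genome=5e-3, horizon=3000)
        cfg_ben = SimConfig(dfe=(DFEClass(+0.05, 1.0),), **base)
        cfg_del = SimConfig(dfe=(DFEClass(-0.05, 1.0),), **base)
        gens = {}
        for name, cfg in [("ben", cfg_ben), ("del", cfg_del)]:
            outs = [run_replicate(cfg, s)
                    for s in np.random.SeedSequence(5).spawn(40)]
            fixed = [o.fix_generation for o in outs if o.fixed]
            assert len(fixed) >= 10
            gens[name] = np.array(fixed, dtype=float)
        se = np.sqrt(gens["ben"].var(ddof=1) / gens["ben"].size
                     + gens["del"].var(ddof=1) / gens["del"].size)
        assert gens["del"].mean() <= gens["ben"].mean() + 3 * se


class TestSummaries:
    def test_substitution_frequency_trivial_cases(self):
        fixed = [ReplicateOutcome(True, 10, 1.0)] * 5
        lost = [ReplicateOutcome(False, None, 0.0)] * 5
        s_all = substitution_frequency(fixed, seed=1)
        assert (s_all.f_s, s_all.ci_low, s_all.ci_high) == (1.0, 1.0, 1.0)
        s_none = substitution_frequency(lost, seed=1)
        assert (s_none.f_s, s_none.ci_low, s_none.ci_high) == (0.0, 0.0, 0.0)
        s_half = substitution_frequency(fixed * 2 + lost * 2, seed=1)
        assert s_half.f_s == 0.5

    def test_empty_outcome_list_rejected(self):
        with pytest.raises(ValueError):
            substitution_frequency([])

    def test_summary_bound_ordering_enforced(self):
        with pytest.raises(ValueError):
            FixationSummary(f_s=0.5, ci_low=0.6, ci_high=0.9, n_reps=10)

    @pytest.mark.parametrize("f2k, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.75)])
    def test_two_epoch_extrapolation(self, f2k, expected):
        assert extrapolate_fluctuating(f2k) == pytest.approx(expected)

    def test_extrapolation_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            extrapolate_fluctuating(1.2)

    @pytest.mark.parametrize("args, expected",
                             [((1.0, 1.0), 1.0), ((0.0, 0.0), 0.0),
                              ((0.9, 0.7), (0.9 + 2 * 0.91) / 3)])
    def test_combined_three_regime_frequency(self, args, expected):
        assert combined_fs(*args) == pytest.approx(expected, abs=1e-9)

    def test_sweep_single_size_single_rep(self):
        cfg = small_config(horizon=20)
        out = sweep_population_sizes(cfg, [100], reps=1, seed=4)
        assert len(out) == 1 and out[0].n_reps == 1

    def test_sweep_duplicate_sizes_use_independent_seed_streams(self, monkeypatch):
        seen = []
        real = wf.run_replicate

        def recorder(cfg, seed, checkpoints=()):
            seen.append(repr(seed))  # SeedSequence repr includes spawn_key
            return real(cfg, seed, checkpoints)

        monkeypatch.setattr(wf, "run_replicate", recorder)
        cfg = small_config(horizon=5)
        sweep_population_sizes(cfg, [100, 100], reps=3, seed=9)
        first, second = seen[:3], seen[3:]
        assert set(first).isdisjoint(set(second))
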