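"""Synthetic laboratory-input generators."""

import json
import math

import numpy as np
import pytest

from contingency_lab.fitness import relative_fitness
from contingency_lab.growth import GrowthParams, br_trajectory
from contingency_lab.similarity import group_mean_similarity
from contingency_lab.synthetic import (
    NoiseModel, gen_competition_counts, gen_fluctuation_counts,
    gen_growth_curve, gen_mutation_profiles, save_table,
)

STD = GrowthParams(y0=0.003, r=0.8, k=0.3, nu=1.0, q0=4.54e-5, v=2.0)


class TestGrowthCurves:
    def test_zero_noise_first_reading_equals_initial_density(self):
        df = gen_growth_curve(STD, 24, 5, NoiseModel(od_sd=0.0), seed=0)
        assert df["od"].iloc[0] == STD.y0

    def test_five_minute_sampling_gives_289_rows_over_24h(self):
        df = gen_growth_curve(STD, 24, 5, NoiseModel(), seed=0)
        assert len(df) == 289
        assert df["time_h"].iloc[0] == 0.0

    def test_fully_activated_curve_matches_logistic_closed_form(self):
        p = GrowthParams(y0=0.003, r=0.8, k=0.3, nu=1.0, q0=1e9, v=1.0)
        df = gen_growth_curve(p, 24, 5, NoiseModel(), seed=0)
        t = df["time_h"].to_numpy()
        logistic = p.k * p.y0 * np.exp(p.r * t) / (p.k + p.y0 * (np.exp(p.r * t) - 1))
        assert np.abs(df["od"].to_numpy() - logistic).max() < 1e-6

    def test_noise_sd_calibrated(self):
        # residual SD within 10% of the requested noise at 10^4 readings
        sd = 0.01
        p = GrowthParams(y0=0.1, r=0.8, k=0.3, nu=1.0, q0=1.0, v=1.0)
        df = gen_growth_curve(p, 1000, 6, NoiseModel(od_sd=sd), seed=12)
        clean = br_trajectory(p, df["time_h"].to_numpy())
        resid = df["od"].to_numpy() - clean
        assert abs(resid.std(ddof=1) - sd) < 0.1 * sd

    def test_same_seed_identical_table(self):
        a = gen_growth_curve(STD, 8, 5, NoiseModel(od_sd=0.01), seed=3)
        b = gen_growth_curve(STD, 8, 5, NoiseModel(od_sd=0.01), seed=3)
        assert a.equals(b)

    def test_non_positive_horizon_or_interval_rejected(self):
        with pytest.raises(ValueError):
            gen_growth_curve(STD, 0, 5, NoiseModel(), 0)
        with pytest.raises(ValueError):
            gen_growth_curve(STD, 24, -5, NoiseModel(), 0)


class TestFluctuationCounts:
    def test_zero_rate_all_zero(self):
        assert gen_fluctuation_counts(0.0, 10**6, 20, seed=1).sum() == 0

    def test_zero_fraction_matches_poisson_law(self):
        # P(no mutation events) = e^-m at m = 1
        m = 1.0
        n_cult = 10_000
        counts = gen_fluctuation_counts(m / 2**14, 2**14, n_cult, seed=5)
        frac0 = (counts == 0).mean()
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / n_cult)
        assert abs(frac0 - math.exp(-1.0)) < 3 * se

    def test_heavy_tail_mean_exceeds_event_number(self):
        counts = gen_fluctuation_counts(2.0 / 2**16, 2**16, 5000, seed=6)
        assert counts.mean() > 2.0

    def test_same_seed_identical_counts(self):
        a = gen_fluctuation_counts(1e-5, 2**15, 30, seed=9)
        b = gen_fluctuation_counts(1e-5, 2**15, 30, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_fluctuation_counts(-0.1, 100, 5, 0)
        with pytest.raises(ValueError):
            gen_fluctuation_counts(1.0, 100, 5, 0)


class TestCompetitionCounts:
    def test_neutral_no_noise_frequencies_equal(self):
        assay = gen_competition_counts(1.0, 1000, 1000, d=1, seed=0,
                                       noise=NoiseModel(count_sampling="none"))
        f_init = assay.n_a_initial / (assay.n_a_initial + assay.n_b_initial)
        f_fin = assay.n_a_final / (assay.n_a_final + assay.n_b_final)
        assert f_init == pytest.approx(f_fin, abs=1e-12)

    def test_estimator_inverts_generator(self):
        assay = gen_competition_counts(1.083, 10**6, 10**6, d=1, seed=3)
        assert relative_fitness(assay).w_rel == pytest.approx(1.083, rel=0.01)

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            gen_competition_counts(1.0, 100, 100, d=0, seed=0)

    def test_non_positive_fitness_rejected(self):
        with pytest.raises(ValueError):
            gen_competition_counts(0.0, 100, 100, d=1, seed=0)


class TestMutationProfiles:
    def test_saturated_probabilities_identical_clones(self):
        profs = gen_mutation_profiles(4, 4, 20, 1.0, 1.0, seed=0)
        res = group_mean_similarity(profs)
        assert res.within["A"] == res.within["B"] == res.between == pytest.approx(1.0)

    def test_private_loci_only_disjoint_clones(self):
        profs = gen_mutation_profiles(3, 3, 20, 0.0, 0.0, seed=0, n_private=2)
        res = group_mean_similarity(profs)
        assert res.within["A"] == res.within["B"] == res.between == pytest.approx(0.0)

    def test_within_exceeds_between_in_expectation(self):
        # Monte-Carlo check of the documented expectation ordering
        within, between = [], []
        for s in np.random.SeedSequence(31).spawn(200):
            profs = gen_mutation_profiles(4, 4, 30, 0.5, 0.1, seed=s, n_private=1)
            res = group_mean_similarity(profs)
            within.append((res.within["A"] + res.within["B"]) / 2)
            between.append(res.between)
        assert np.mean(within) > np.mean(between)

    def test_null_setting_is_exchangeable_construction(self):
        # p_within == p_shared: all clones share one inclusion probability
        profs = gen_mutation_profiles(5, 5, 40, 0.2, 0.2, seed=11)
        sizes = [len(p.loci) for p in profs]
        assert np.mean(sizes) == pytest.approx(40 * 0.2, rel=0.5)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            gen_mutation_profiles(0, 3, 10, 0.5, 0.5, seed=0)


class TestSidecar:
    def test_csv_and_json_sidecar_written(self, tmp_path):
        df = gen_growth_curve(STD, 2, 10, NoiseModel(), seed=4)
        out = tmp_path / "curve.csv"
        save_table(df, out, {"params": STD, "horizon": 2}, seed=4)
        assert out.exists()
        sidecar = json.loads((tmp_path / "curve.csv.json").read_text())
        assert sidecar["seed"] == 4
        assert sidecar["params"]["params"]["y0"] == STD.y0
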