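import math

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

import cnvlrr as c
from cnvlrr.simulate import (
    DiseaseModel,
    SimulationConfig,
    _noiseless_channels,
    simulate_covariates,
    simulate_phenotype,
)

FREQS = (0.5296, 0.3810, 0.0894)


class TestAssignGenotypes:
    def test_large_sample_frequencies_match(self):
        g = c.assign_genotypes(100_000, FREQS, seed=0)
        observed = np.bincount(g, minlength=3)
        _, p = chisquare(observed, np.array(FREQS) * len(g))
        assert p > 0.001

    def test_null_fraction_near_published_control_rate(self):
        g = c.assign_genotypes(759, FREQS, seed=0)
        se = math.sqrt(0.5296 * (1 - 0.5296) / 759)
        assert abs(np.mean(g == 0) - 0.5296) < 3 * se

    def test_degenerate_distribution(self):
        assert (c.assign_genotypes(50, (0, 0, 1), seed=0) == 2).all()

    def test_invalid_probability_names_entry(self):
        with pytest.raises(ValueError, match=r"class_freqs\[1\]"):
            c.assign_genotypes(10, (0.5, 1.3, -0.8), seed=0)

    @pytest.mark.parametrize("n", [500, 2000])
    def test_frequencies_within_three_se(self, n):
        g = c.assign_genotypes(n, FREQS, seed=3)
        for k, f in enumerate(FREQS):
            se = math.sqrt(f * (1 - f) / n)
            assert abs(np.mean(g == k) - f) <= 3 * se


class TestNoiselessIntensities:
    def test_symmetric_heterozygote(self):
        X, Y = _noiseless_channels(np.array([2]), np.array([1]), 1.0, 0.0)
        assert X[0] == pytest.approx(0.5)
        assert Y[0] == pytest.approx(0.5)

    def test_null_sample_total_is_background(self):
        X, Y = _noiseless_channels(np.array([0]), np.array([0]), 1.0, 0.095)
        assert X[0] == pytest.approx(0.0475)
        assert Y[0] == pytest.approx(0.0475)
        assert X[0] + Y[0] == pytest.approx(0.095)

    def test_one_copy_reference_lrr_closest_to_one_copy_state(self):
        X, Y = _noiseless_channels(np.array([1]), np.array([0]), 1.0, 0.095)
        r = X[0] + Y[0]
        assert r == pytest.approx(0.595)
        lrr = math.log2(r / 1.095)
        assert lrr == pytest.approx(-0.88, abs=0.005)
        state_means = (-3.53, -0.66, 0.0, 0.40, 0.68)
        assert int(np.argmin(np.abs(np.array(state_means) - lrr))) == 1

    def test_b_alleles_cannot_exceed_copies(self):
        cohort = c.Cohort(
            sample_id=["a"],
            true_copy_number=np.array([1]),
            b_alleles=np.array([[2, 0, 0, 0, 0]]),
            phenotype=np.array([0]),
            covariates=simulate_covariates(1, np.random.default_rng(0)),
        )
        with pytest.raises(ValueError, match="copy number"):
            c.simulate_intensities(
                cohort, c.default_locus_probes(), SimulationConfig()
            )


class TestPhenotype:
    def _covars(self, n, seed=0):
        return simulate_covariates(n, np.random.default_rng(seed))

    def test_zero_effect_is_independent(self):
        n = 100_000
        g = c.assign_genotypes(n, FREQS, seed=1)
        y = simulate_phenotype(
            g, self._covars(n), DiseaseModel(log_or_effect=0.0), seed=2
        )
        table = np.array(
            [[np.sum((g == k) & (y == d)) for k in (0, 2)] for d in (0, 1)]
        )
        or_hat = (table[1, 1] * table[0, 0]) / (table[1, 0] * table[0, 1])
        assert or_hat == pytest.approx(1.0, abs=0.08)

    def test_trend_effect_recovers_per_copy_or(self):
        n = 100_000
        g = c.assign_genotypes(n, FREQS, seed=4)
        y = simulate_phenotype(
            g, self._covars(n),
            DiseaseModel(mode="trend", log_or_effect=math.log(0.74)),
            seed=5,
        )
        # per-copy OR from adjacent 2x2 tables (0 vs 1 copies)
        a = np.sum((g == 1) & (y == 1)) * np.sum((g == 0) & (y == 0))
        b = np.sum((g == 1) & (y == 0)) * np.sum((g == 0) & (y == 1))
        assert a / b == pytest.approx(0.74, abs=0.03)

    def test_two_class_effect_null_vs_carrier(self):
        n = 100_000
        g = c.assign_genotypes(n, FREQS, seed=6)
        y = simulate_phenotype(
            g, self._covars(n),
            DiseaseModel(mode="two_class", log_or_effect=math.log(0.66)),
            seed=7,
        )
        carrier = g > 0
        a = np.sum(~carrier & (y == 1)) * np.sum(carrier & (y == 0))
        b = np.sum(~carrier & (y == 0)) * np.sum(carrier & (y == 1))
        assert a / b == pytest.approx(1 / 0.66, abs=0.06)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            DiseaseModel(mode="dominant")

    def test_null_effect_chisquare_pvalues_uniform(self):
        # genotype-phenotype independence across seeded replicates
        from scipy.stats import chi2_contingency

        pvals = []
        for rep in range(200):
            g = c.assign_genotypes(400, FREQS, seed=1000 + rep)
            y = simulate_phenotype(
                g, self._covars(400, seed=rep),
                DiseaseModel(log_or_effect=0.0), seed=2000 + rep,
            )
            tab = np.array(
                [[np.sum((g == k) & (y == d)) for k in range(3)]
                 for d in (0, 1)]
            )
            pvals.append(chi2_contingency(tab)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSimulateCohort:
    def test_default_fixture_dimensions(self, calling_fixture):
        cfg, cohort, raw, probes = calling_fixture
        assert cohort.n == 1532
        assert sum(p.is_locus_probe for p in probes) == 5
        assert raw.X.shape == (cohort.n, len(probes))
        assert (cohort.phenotype == 1).sum() == 773
        assert (cohort.phenotype == 0).sum() == 759

    def test_full_panel_size(self):
        probes = c.build_probe_panel(2000)
        assert len(probes) == 2005
        pos = [p.position for p in probes]
        assert pos == sorted(pos)

    def test_locus_probe_coordinates(self):
        locus = c.default_locus_probes()
        assert [p.probe_id for p in locus][0] == "rs12068997"
        assert [p.position for p in locus] == [
            110_032_359, 110_034_047, 110_034_670, 110_034_988, 110_035_809
        ]

    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=9, n_cases=40, n_controls=40,
                               n_background_probes=10)
        c1_, r1, _ = c.simulate_cohort(cfg)
        c2_, r2, _ = c.simulate_cohort(cfg)
        assert np.array_equal(c1_.true_copy_number, c2_.true_copy_number)
        assert np.array_equal(r1.X, r2.X) and np.array_equal(r1.Y, r2.Y)

    def test_seed_changes_genotypes(self):
        a, _, _ = c.simulate_cohort(
            SimulationConfig(seed=9, n_cases=200, n_controls=200,
                             n_background_probes=5)
        )
        b, _, _ = c.simulate_cohort(
            SimulationConfig(seed=10, n_cases=200, n_controls=200,
                             n_background_probes=5)
        )
        assert not np.array_equal(a.true_copy_number, b.true_copy_number)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(genotype_class_freqs=(0.5, 0.4, 0.2)).validate()
        with pytest.raises(ValueError, match=r"genotype_class_freqs\[0\]"):
            SimulationConfig(
                genotype_class_freqs=(1.4, -0.5, 0.1)
            ).validate()
        with pytest.raises(ValueError, match="counts"):
            SimulationConfig(n_cases=0, n_controls=0).validate()

    def test_intensities_nonnegative(self, calling_fixture):
        _, _, raw, _ = calling_fixture
        assert raw.X.min() >= 0 and raw.Y.min() >= 0

    def test_compressed_regime_class_means(self):
        cfg = c.concordance_fixture(seed=3, n_background_probes=10)
        cohort, raw, probes = c.simulate_cohort(cfg)
        locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
        lrr = np.log2((raw.X + raw.Y)[:, locus] / 1.095)
        for k, target in enumerate(cfg.compressed_class_means):
            m = cohort.true_copy_number == k
            assert lrr[m].mean() == pytest.approx(target, abs=0.02)
            assert lrr[m].std() == pytest.approx(cfg.lrr_noise_sd, abs=0.02)
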