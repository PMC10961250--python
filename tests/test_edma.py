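"""EDMA form comparison: mean forms, FDM ratios, bootstrap CIs, binning."""

import numpy as np
import pytest

from chondromorph.edma import (
    GroupSample,
    bootstrap_difference_ci,
    classify_differences,
    difference_to_frame,
    form_difference_matrix,
    mean_form_matrix,
)
from chondromorph.synth import (
    MC_MEAN,
    Effect,
    PopulationSpec,
    default_sigma,
    generate_landmark_population,
    planted_distance_ratios,
)

from conftest import make_config, make_group

ALL_MC = tuple(MC_MEAN)


def two_point_group(distances, label="g", genotype="wildtype"):
    """One specimen per distance value: two landmarks `d` apart."""
    return make_group([{"mca": (0, 0, 0), "mcsym": (d, 0, 0)}
                       for d in distances], label=label, genotype=genotype)


class TestMeanForm:
    def test_identical_configurations_exact(self, mc_mean):
        group = make_group([mc_mean] * 4)
        fm = mean_form_matrix(group)
        expected = make_config(mc_mean)
        from chondromorph.landmarks import interlandmark_distances
        np.testing.assert_array_equal(fm.distances,
                                      interlandmark_distances(expected).distances)

    def test_arithmetic_and_rms_closed_form(self):
        group = two_point_group([3.0, 5.0])
        assert mean_form_matrix(group, "arithmetic").distances[0] == pytest.approx(4.0)
        assert mean_form_matrix(group, "rms").distances[0] == pytest.approx(np.sqrt(17))

    def test_monte_carlo_consistency(self):
        # n=1000 Gaussian-perturbed specimens: arithmetic mean within 0.5%
        # of the exact population mean distance.  The distance between two
        # landmarks with iid N(0, sigma^2 I3) noise is sigma*sqrt(2) times a
        # noncentral chi(3) variate, whose mean is the independent oracle
        # (numerical integration of the noncentral chi-square density).
        from scipy.integrate import quad
        from scipy.stats import ncx2

        from chondromorph.landmarks import interlandmark_distances

        def expected_distance(d, sigma):
            s = sigma * np.sqrt(2.0)  # sd of each coordinate difference
            rv = ncx2(df=3, nc=(d / s) ** 2)
            val, _ = quad(lambda y: np.sqrt(y) * rv.pdf(y), 0,
                          rv.ppf(1 - 1e-13))
            return s * val

        sigma = 0.01 * default_sigma(MC_MEAN) / 0.02  # 1% of mean distance
        group = generate_landmark_population(
            PopulationSpec(mean=MC_MEAN, sigma=sigma, n=1000, seed=123))
        fm = mean_form_matrix(group)
        noiseless = interlandmark_distances(make_config(MC_MEAN)).distances
        truth = np.array([expected_distance(d, sigma) for d in noiseless])
        np.testing.assert_allclose(fm.distances, truth, rtol=5e-3)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            GroupSample(label="g", configurations=[])


class TestFormDifference:
    def test_identity(self, mc_mean):
        g = make_group([mc_mean] * 3)
        dm = form_difference_matrix(g, g)
        np.testing.assert_array_equal(dm.ratio, np.ones(15))

    def test_uniform_scaling_exact(self, mc_mean):
        g = make_group([mc_mean] * 3)
        scaled = make_group([{a: tuple(1.2 * np.asarray(x) for x in [v])[0]
                              for a, v in mc_mean.items()}] * 3,
                            label="m", genotype="mutant")
        dm = form_difference_matrix(scaled, g)
        np.testing.assert_allclose(dm.ratio, 1.2, rtol=1e-12)

    def test_planted_block_recovered_within_bands(self):
        # sigma=0.02, n=20/group: every ratio within 3% of the exact
        # generator-side oracle ratio for the planted 1.2x block
        block = ("mca", "mcpl", "mcpr")
        effects = (Effect(block, 1.2),)
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 20, genotype="mutant", effects=effects, seed=17))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 20, seed=18))
        dm = form_difference_matrix(num, den)
        labels, oracle = planted_distance_ratios(MC_MEAN, effects)
        assert labels == dm.labels
        np.testing.assert_allclose(dm.ratio, oracle, rtol=0.03)
        block_pairs = [k for k, (a, b) in enumerate(labels)
                       if a in block and b in block]
        assert np.all(oracle[block_pairs] == pytest.approx(1.2))

    def test_reciprocity(self):
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 5, genotype="mutant", seed=1))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 5, seed=2))
        fwd = form_difference_matrix(num, den)
        rev = form_difference_matrix(den, num)
        np.testing.assert_allclose(rev.ratio, 1.0 / fwd.ratio, rtol=1e-12)

    def test_scale_equivariance(self):
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 5, genotype="mutant", seed=3))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 5, seed=4))
        base = form_difference_matrix(num, den).ratio
        s = 1.7
        scaled_configs = [
            make_config({a: np.asarray(x) * s for a, x in c.coordinates.items()},
                        specimen=c.specimen_id, genotype="mutant")
            for c in num.configurations]
        scaled = GroupSample(label="scaled", configurations=scaled_configs)
        np.testing.assert_allclose(form_difference_matrix(scaled, den).ratio,
                                   s * base, rtol=1e-12)


class TestBootstrap:
    def test_reproducible_bit_identical(self):
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 5, genotype="mutant", seed=5))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.02, 4, seed=6))
        a = bootstrap_difference_ci(num, den, n_boot=500, seed=99)
        b = bootstrap_difference_ci(num, den, n_boot=500, seed=99)
        np.testing.assert_array_equal(a.ratio, b.ratio)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)

    def test_degenerate_groups_unit_cis(self, mc_mean):
        num = make_group([mc_mean] * 3, label="m", genotype="mutant")
        den = make_group([mc_mean] * 3)
        dm = bootstrap_difference_ci(num, den, n_boot=200, seed=0)
        np.testing.assert_array_equal(dm.ratio, 1.0)
        np.testing.assert_array_equal(dm.ci_low, 1.0)
        np.testing.assert_array_equal(dm.ci_high, 1.0)
        assert not dm.significant.any()

    def test_high_signal_all_planted_flagged(self):
        effects = (Effect(ALL_MC, 1.3),)
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.01, 5, genotype="mutant", effects=effects, seed=7))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.01, 5, seed=8))
        dm = bootstrap_difference_ci(num, den, alpha=0.10, n_boot=1000, seed=7)
        assert dm.significant.all()

    def test_ci_contains_point_estimate(self):
        num = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.03, 6, genotype="mutant", seed=9))
        den = generate_landmark_population(PopulationSpec(
            MC_MEAN, 0.03, 5, seed=10))
        dm = bootstrap_difference_ci(num, den, n_boot=2000, seed=11)
        assert np.all(dm.ci_low <= dm.ratio + 1e-12)
        assert np.all(dm.ratio <= dm.ci_high + 1e-12)

    def test_small_n_boot_warns(self, mc_mean):
        g = make_group([mc_mean] * 2)
        m = make_group([mc_mean] * 2, label="m", genotype="mutant")
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_difference_ci(m, g, n_boot=50, seed=0)

    def test_single_specimen_errors(self, mc_mean):
        g = make_group([mc_mean] * 2)
        single = make_group([mc_mean], label="m", genotype="mutant")
        with pytest.raises(ValueError, match="n >= 2"):
            bootstrap_difference_ci(single, g, seed=0)


class TestClassification:
    def _dm(self, ratios, significant):
        from chondromorph.edma import DifferenceMatrix
        labels = tuple((f"a{i}", f"b{i}") for i in range(len(ratios)))
        ratios = np.asarray(ratios, dtype=float)
        lo = np.where(significant, np.where(ratios > 1, 1.01, ratios - 0.01),
                      ratios - 0.5)
        hi = np.where(significant, np.where(ratios > 1, ratios + 0.01, 0.99),
                      ratios + 0.5)
        return DifferenceMatrix(labels, ratios, "m", "w", alpha=0.1,
                                n_boot=100, ci_low=lo, ci_high=hi)

    def test_direct_binning(self):
        dm = self._dm([1.07, 1.20, 0.96], [True, True, True])
        bc = classify_differences(dm)
        counts = bc.counts()
        assert counts["larger"]["5%-10%"] == 1
        assert counts["larger"][">=11%"] == 1
        assert counts["smaller"]["<5%"] == 1

    def test_rounded_ten_percent_in_lower_bin(self):
        bc = classify_differences(self._dm([1.104], [True]))
        assert bc.counts()["larger"]["5%-10%"] == 1

    def test_all_null_empty_bins(self):
        dm = self._dm([1.0, 1.0], [False, False])
        counts = classify_differences(dm).counts()
        assert all(v == 0 for side in counts.values() for v in side.values())

    def test_every_significant_pair_in_exactly_one_bin(self):
        rng = np.random.default_rng(0)
        ratios = rng.uniform(0.7, 1.4, size=40)
        dm = self._dm(ratios, np.ones(40, bool))
        bc = classify_differences(dm)
        binned = [p for side in (bc.larger, bc.smaller)
                  for pairs in side.values() for p in pairs]
        assert sorted(binned) == sorted(dm.labels)

    def test_frame_export_has_bins(self):
        dm = self._dm([1.07, 0.96], [True, True])
        df = difference_to_frame(dm, classify_differences(dm))
        assert set(df.columns) >= {"ratio", "ci_low", "ci_high",
                                   "significant", "bin"}
        assert df["bin"].str.len().gt(0).all()
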