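"""Objective curves, the argmax search, and their independent oracles."""

import itertools

import numpy as np
import pytest

from skewotsu import (
    Histogram,
    log_means,
    otsu_gaussian_curve,
    otsu_lognormal_curve,
    otsu_modified_curve,
    threshold_image,
)
from skewotsu.thresholding import between_class_curve_explicit, log_bin_values

from conftest import assert_same_argmax, random_histogram


def spike(levels: int, **mass: int) -> Histogram:
    counts = np.zeros(levels, dtype=np.int64)
    for key, v in mass.items():
        counts[int(key.lstrip("b"))] = v
    return Histogram(counts)


class TestGaussianCurve:
    def test_rational_form_equals_explicit_form(self, rng):
        """The one-pass rational form must reproduce the two-term definition."""
        for _ in range(100):
            h = random_histogram(rng)
            fast = otsu_gaussian_curve(h).values
            slow = between_class_curve_explicit(h)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_exhaustive_small_alphabet(self):
        """Every histogram of 6 pixels over 8 levels: argmax agrees with brute force."""
        for combo in itertools.combinations_with_replacement(range(8), 6):
            counts = np.bincount(combo, minlength=8).astype(np.int64)
            h = Histogram(counts)
            curve = otsu_gaussian_curve(h)
            slow = between_class_curve_explicit(h)
            np.testing.assert_allclose(curve.values, slow, rtol=1e-9, atol=1e-12)
            assert_same_argmax(curve.values, slow)

    def test_two_spike_ties_break_to_smallest(self, two_spike):
        curve = otsu_gaussian_curve(two_spike)
        assert curve.t_star == 50
        # flat over the whole tie region
        assert np.all(curve.values[50:200] == curve.values[50])

    def test_matches_reference_implementation(self, rng):
        """t* equals scikit-image's Otsu threshold on seeded images."""
        from skimage.filters import threshold_otsu

        for _ in range(20):
            mu1, mu2 = rng.uniform(30, 90), rng.uniform(120, 220)
            img = np.concatenate(
                [rng.normal(mu1, 15, 3000), rng.normal(mu2, 25, 2000)]
            )
            img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(50, 100)
            t = otsu_gaussian_curve(Histogram.from_image(img)).t_star
            assert t == int(threshold_otsu(img))

    def test_single_bin_is_flat_zero(self):
        curve = otsu_gaussian_curve(spike(256, b77=10))
        assert np.all(curve.values == 0.0) and curve.t_star == 0 and curve.degenerate


class TestLogMeans:
    def test_all_mass_at_zero(self):
        lm = log_means(spike(256, b0=5), 100)
        assert lm.mu_total_log == 0.0  # log(0+1)

    def test_single_bin_mass(self):
        lm = log_means(spike(256, b6=5), 100)
        assert lm.mu_total_log == pytest.approx(np.log(7), abs=1e-12)

    def test_two_spike_direct_sum(self, two_spike):
        lm = log_means(two_spike, 100)
        assert lm.mu_object_log == pytest.approx(np.log(51))
        assert lm.mu_background_log == pytest.approx(np.log(201))
        assert lm.mu_total_log == pytest.approx(0.5 * (np.log(51) + np.log(201)))

    def test_weighted_mean_decomposition(self, rng):
        """Po*mu_o,log + Pb*mu_b,log recovers the total log-mean."""
        from skewotsu import class_stats

        for _ in range(20):
            h = random_histogram(rng)
            t = int(rng.integers(0, 256))
            lm = log_means(h, t)
            if lm.degenerate:
                continue
            cs = class_stats(h, t)
            assert (
                cs.p_object * lm.mu_object_log + cs.p_background * lm.mu_background_log
            ) == pytest.approx(lm.mu_total_log, abs=1e-9)

    def test_skip_zero_map_excludes_bin_zero(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = 50
        counts[10] = 50
        lm = log_means(Histogram(counts), 5, log_map="skip-zero")
        assert lm.mu_background_log == pytest.approx(np.log(10))
        assert lm.mu_total_log == pytest.approx(np.log(10))  # bin 0 carries no log weight


class TestLognormalCurve:
    def test_equivalence_with_log_mapped_gaussian_oracle(self, rng):
        """Central correctness check: the log-domain objective is the Gaussian
        between-class variance computed on bin values log(i+1)."""
        lam, _ = log_bin_values(256)
        for _ in range(100):
            h = random_histogram(rng)
            curve = otsu_lognormal_curve(h)
            oracle = between_class_curve_explicit(h, bin_values=lam)
            np.testing.assert_allclose(curve.values, oracle, rtol=1e-9, atol=1e-12)
            assert_same_argmax(curve.values, oracle)

    def test_single_bin_is_flat_zero(self):
        assert np.all(otsu_lognormal_curve(spike(256, b9=4)).values == 0.0)

    def test_padding_with_empty_high_bins_preserves_argmax(self, rng):
        h = random_histogram(rng, levels=128)
        t1 = otsu_lognormal_curve(h).t_star
        padded = Histogram(np.concatenate([h.counts, np.zeros(128, dtype=np.int64)]))
        assert otsu_lognormal_curve(padded).t_star == t1

    def test_threshold_near_misclassification_optimum_on_separated_mixture(self):
        """On cleanly separated mixtures t* falls in the minimal-error valley."""
        from skewotsu import WELL_SEPARATED_TEMPLATE, generate_dataset

        for s in generate_dataset(5, WELL_SEPARATED_TEMPLATE, seed=11):
            h = Histogram.from_image(s.image)
            t = otsu_lognormal_curve(h).t_star
            errors = np.array(
                [np.sum((s.image > tt) != s.truth.pixels) for tt in range(256)]
            )
            minimizers = np.flatnonzero(errors == errors.min())
            assert np.min(np.abs(minimizers - t)) <= 2


class TestModifiedCurve:
    def test_single_bin_is_flat_zero(self):
        assert np.all(otsu_modified_curve(spike(256, b3=9)).values == 0.0)

    def test_rational_equals_two_term_form(self, rng):
        """The rational form with log-means is algebraically the explicit
        between-class variance of log-intensities."""
        for _ in range(100):
            h = random_histogram(rng)
            a = otsu_modified_curve(h).values
            b = otsu_lognormal_curve(h).values
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_two_spike_argmax_unchanged_by_log_map(self, two_spike):
        assert otsu_modified_curve(two_spike).t_star == 50


class TestThresholdImage:
    def test_two_valued_image_separates_exactly(self):
        img = np.full((10, 10), 50, dtype=np.uint8)
        img[:, 5:] = 200
        for method in ("otsu_gaussian", "otsu_modified", "otsu_lognormal"):
            res = threshold_image(img, method)
            assert np.array_equal(res.mask.pixels, img == 200)

    def test_constant_image_degenerate(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        with pytest.warns(UserWarning, match="degenerate"):
            res = threshold_image(img, "otsu_gaussian")
        assert res.degenerate and res.t_star == 0
        assert not res.mask.pixels.any()

    def test_invert_flips_polarity(self):
        img = np.full((4, 4), 50, dtype=np.uint8)
        img[0] = 200
        res = threshold_image(img, "otsu_gaussian", invert=True)
        assert np.array_equal(res.mask.pixels, img <= res.t_star)
        assert res.mask.polarity == "below"

    def test_deterministic_across_reruns(self, rng):
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        for method in ("otsu_gaussian", "otsu_modified", "otsu_lognormal"):
            r1 = threshold_image(img, method)
            r2 = threshold_image(img, method)
            assert r1.t_star == r2.t_star
            assert np.array_equal(r1.curve.values, r2.curve.values)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            threshold_image(np.zeros((2, 2), dtype=np.uint8), "median")


def test_curves_are_finite_and_nonnegative(rng):
    for _ in range(20):
        h = random_histogram(rng)
        for curve in (otsu_gaussian_curve(h), otsu_modified_curve(h), otsu_lognormal_curve(h)):
            assert curve.values.size == 256
            assert np.all(np.isfinite(curve.values))
            assert np.all(curve.values >= 0.0)


def test_all_methods_agree_on_two_spike(two_spike):
    assert (
        otsu_gaussian_curve(two_spike).t_star
        == otsu_modified_curve(two_spike).t_star
        == otsu_lognormal_curve(two_spike).t_star
        == 50
    )


def test_curve_csv_output(tmp_path, two_spike):
    import pandas as pd

    curve = otsu_gaussian_curve(two_spike)
    curve.to_csv(tmp_path / "c.csv")
    df = pd.read_csv(tmp_path / "c.csv")
    assert list(df.columns) == ["t", "value"] and len(df) == 256
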