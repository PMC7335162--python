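"""Second-derivative statistic, propagated thresholds and band detection."""

import numpy as np
import pytest

from foramxrf import (
    EXACT_SQRT6,
    PAPER_FACTOR2,
    Profile,
    RatioProfile,
    d2_uncertainty,
    detect_bands,
    ratio_profile,
    second_derivative,
)
from foramxrf.band_detection import BandDetectionError, ENRICHED
from foramxrf.wall_model import expected_element_maps, default_acquisition


def make_ratio(values, dx=1.0, sigma=1.0):
    values = np.asarray(values, dtype=float)
    pos = (np.arange(values.size) + 0.5) * dx
    sig = np.full_like(values, sigma)
    return RatioProfile("Mn", "Ca", pos, values, sig)


class TestSecondDerivative:
    def test_linear_profile_has_zero_curvature(self):
        rp = make_ratio(3.0 + 0.5 * np.arange(20))
        d2p = second_derivative(rp)
        assert np.allclose(d2p.d2, 0.0, atol=1e-12)
        assert d2p.position.size == 18

    def test_quadratic_profile_is_exact(self):
        x = np.arange(20, dtype=float) + 0.5
        rp = make_ratio(x**2, dx=1.0)
        d2p = second_derivative(rp)
        assert np.allclose(d2p.d2, 2.0, rtol=1e-12)

    @pytest.mark.parametrize("n", [100, 200, 400])
    def test_sinusoid_error_shrinks_quadratically(self, n):
        omega = 2 * np.pi / 10.0
        dx = 100.0 / n
        x = (np.arange(n) + 0.5) * dx
        rp = RatioProfile("Mn", "Ca", x, np.sin(omega * x),
                          np.full(n, 1e-9))
        d2p = second_derivative(rp)
        err = np.max(np.abs(d2p.d2 + omega**2 * np.sin(omega *
                                                       d2p.position)))
        # central differences: error ~ (omega*dx)^2 / 12 * omega^2
        bound = omega**4 * dx**2 / 12 * 1.5
        assert err < bound

    def test_non_uniform_spacing_rejected(self):
        pos = np.array([0.0, 1.0, 2.5, 3.0])
        rp = RatioProfile("Mn", "Ca", pos, np.ones(4), np.ones(4))
        with pytest.raises(BandDetectionError, match="uniform"):
            second_derivative(rp)


class TestUncertainty:
    def test_exact_propagation_for_constant_sigma(self):
        s = 0.01
        rp = make_ratio(np.ones(10), sigma=s)
        sigma_d2, threshold = d2_uncertainty(rp, EXACT_SQRT6)
        assert np.allclose(sigma_d2, np.sqrt(6) * s)
        assert threshold == pytest.approx(np.sqrt(6) * s)

    def test_factor2_to_exact_ratio(self):
        rp = make_ratio(np.ones(10), sigma=0.02)
        _, t2 = d2_uncertainty(rp, PAPER_FACTOR2)
        _, t6 = d2_uncertainty(rp, EXACT_SQRT6)
        assert t2 / t6 == pytest.approx(2 / np.sqrt(6))

    def test_unknown_method_rejected(self):
        rp = make_ratio(np.ones(10))
        with pytest.raises(BandDetectionError, match="method"):
            d2_uncertainty(rp, "bootstrap")

    def test_exact_formula_matches_monte_carlo(self, rng):
        """Empirical SD of d2 over 1e5 Poisson ratio replicates."""
        sx, sy, width = 2500.0, 1.0e6, 21
        n_rep = 100000
        raw_x = rng.poisson(sx * width, size=(n_rep, 3))
        raw_y = rng.poisson(sy * width, size=(n_rep, 3))
        r = (raw_x / width) / (raw_y / width)
        dx = 60.0
        d2 = (r[:, 2] - 2 * r[:, 1] + r[:, 0]) / dx**2
        empirical = d2.std(ddof=1)
        sigma_ratio = (sx / sy) * np.sqrt(1 / (width * sx)
                                          + 1 / (width * sy))
        exact = np.sqrt(6) * sigma_ratio / dx**2
        assert exact == pytest.approx(empirical, rel=0.03)


class TestDetectBands:
    def test_all_zero_curvature_yields_empty_set(self):
        rp = make_ratio(np.full(20, 2.0))
        bands = detect_bands(second_derivative(rp))
        assert bands.bands == []

    def test_sinusoid_band_count_widths_and_significance(self):
        period, dx, n = 20.0, 1.0, 200
        x = (np.arange(n) + 0.5) * dx
        rp = RatioProfile("Mn", "Ca", x, np.sin(2 * np.pi * x / period),
                          np.full(n, 1e-9))
        bands = detect_bands(second_derivative(rp))
        interior_length = (n - 2) * dx
        expected = int(2 * interior_length / period)
        assert abs(len(bands.bands) - expected) <= 1
        assert all(b.significant for b in bands.bands)
        widths = np.array([b.width for b in bands.bands])
        assert np.all(np.abs(widths - period / 2) <= dx)
        signs = [b.sign for b in bands.bands]
        assert all(a != b for a, b in zip(signs, signs[1:]))

    def test_consecutive_bands_alternate_on_noise(self, rng):
        rp = make_ratio(rng.normal(1.0, 0.01, size=120), sigma=0.01)
        bands = detect_bands(second_derivative(rp))
        signs = [b.sign for b in bands.bands]
        assert all(a != b for a, b in zip(signs, signs[1:]))

    def test_invariant_under_constant_offset(self, rng):
        values = 1.0 + 0.2 * np.sin(np.arange(60) / 3.0)
        b1 = detect_bands(second_derivative(make_ratio(values, sigma=0.01)))
        b2 = detect_bands(second_derivative(make_ratio(values + 5.0,
                                                       sigma=0.01)))
        # the offset perturbs d2 only at float rounding level
        assert len(b1.bands) == len(b2.bands)
        assert np.allclose([b.start for b in b1.bands],
                           [b.start for b in b2.bands], atol=1e-3)
        assert [b.significant for b in b1.bands] == \
            [b.significant for b in b2.bands]

    def test_positive_scaling_scales_d2_and_keeps_flags(self):
        values = 1.0 + 0.2 * np.sin(np.arange(60) / 3.0)
        c = 7.5
        d2a = second_derivative(make_ratio(values, sigma=0.01))
        d2b = second_derivative(make_ratio(c * values, sigma=c * 0.01))
        assert np.allclose(d2b.d2, c * d2a.d2)
        assert np.allclose(d2b.sigma_d2, c * d2a.sigma_d2)
        ba, bb = detect_bands(d2a), detect_bands(d2b)
        assert [b.significant for b in ba.bands] == \
            [b.significant for b in bb.bands]

    def test_pure_noise_profiles_stay_clean_at_three_sigma(self):
        """Short flat Poisson profiles: >= 95/100 have zero significant
        bands at a 3x median-sigma threshold (per-point false-positive
        rate ~0.3%, so family-wise cleanliness holds at this length)."""
        rng = np.random.default_rng(2024)
        n, width, sx, sy = 16, 21, 2500.0, 1.0e6
        clean = 0
        for _ in range(100):
            raw_x = rng.poisson(sx * width, size=n)
            raw_y = rng.poisson(sy * width, size=n)
            pos = (np.arange(n) + 0.5) * 60.0
            px = Profile("Mn", pos, raw_x / width,
                         np.sqrt(raw_x) / width)
            py = Profile("Ca", pos, raw_y / width,
                         np.sqrt(raw_y) / width)
            rp = ratio_profile(px, py)
            d2p = second_derivative(rp, threshold_multiplier=3.0)
            if detect_bands(d2p).n_significant == 0:
                clean += 1
        assert clean >= 95


class TestBandRecovery:
    def test_recall_and_width_on_noise_free_render(self, ytt_model):
        """Every generator Mn band with |d2| > 10x threshold is recovered
        as a significant enriched band of the expected lobe width."""
        acq = default_acquisition(ytt_model, height=3, seed=0)
        expected = expected_element_maps(ytt_model, acq)
        mn, ca = expected["Mn"][1], expected["Ca"][1]
        width = 21
        pos = (np.arange(mn.size) + 0.5) * acq.pixel_size
        p_mn = Profile("Mn", pos, mn, np.sqrt(width * mn) / width)
        p_ca = Profile("Ca", pos, ca, np.sqrt(width * ca) / width)
        rp = ratio_profile(p_mn, p_ca)
        d2p = second_derivative(rp)
        bands = detect_bands(d2p)
        sig_enriched = [b for b in bands.bands
                        if b.significant and b.sign == ENRICHED]

        banding = next(b for b in ytt_model.bandings if b.element == "Mn")
        w, period = banding.band_width, banding.band_period
        centres = []
        for layer in ("ICL", "OCL"):
            lo, hi = ytt_model.layer_interval(layer)
            n_bands = int((hi - lo - w) // period) + 1
            ks = np.arange(n_bands)
            if layer == "ICL":
                centres.extend(lo + w / 2 + ks * period)
            else:
                centres.extend(hi - w / 2 - ks * period)

        dx = acq.pixel_size
        strong = 0
        for c in centres:
            # bands truncated by the profile ends cannot be
            # zero-crossing delimited; skip them
            if c - w / 2 < d2p.position[0] or \
                    c + w / 2 > d2p.position[-1]:
                continue
            near = np.abs(d2p.position - c) < w / 4
            peak = np.max(np.abs(d2p.d2[near]))
            if peak <= 10 * d2p.threshold:
                continue
            strong += 1
            hits = [b for b in sig_enriched if b.start <= c <= b.end]
            assert hits, f"missed generator band at {c:.0f} nm"
            # the enriched lobe of a raised-cosine band spans w/2
            assert abs(hits[0].width - w / 2) <= 2 * dx
        assert strong > 0
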