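"""Wall-model presets, concentration fields and Poisson rendering."""

import numpy as np
import pytest

from foramxrf import (
    AcquisitionSpec,
    BandingSpec,
    LayerSpec,
    WallModel,
    WallModelError,
    concentration_profile,
    default_acquisition,
    default_wall_model,
    expected_bulk_counts,
    expected_element_maps,
    render_bulk_counts,
    render_element_maps,
)
from foramxrf.wall_model import YTT_TO_MODERN_BULK_MN, _mean_concentration


class TestPresets:
    def test_ytt_poz_thickness_in_reported_range(self, ytt_model):
        lo, hi = ytt_model.layer_interval("POZ")
        assert 1000.0 <= hi - lo <= 1500.0

    def test_ytt_ca_contrast_gc_over_poz(self, ytt_model):
        gc = ytt_model.layers[3].concentration_scale["Ca"]
        poz = ytt_model.layers[1].concentration_scale["Ca"]
        assert gc / poz == pytest.approx(1.5)

    def test_total_thicknesses(self, ytt_model, modern_model):
        assert ytt_model.total_thickness == pytest.approx(15000.0)
        assert modern_model.total_thickness == pytest.approx(5000.0)

    def test_ocl_thicker_than_icl(self, ytt_model, modern_model):
        for model in (ytt_model, modern_model):
            assert model.layers[2].thickness > model.layers[0].thickness

    def test_unknown_kind_rejected(self):
        with pytest.raises(WallModelError):
            default_wall_model("holocene")

    def test_layer_order_enforced(self, ytt_model):
        with pytest.raises(WallModelError):
            WallModel(layers=list(ytt_model.layers)[::-1])

    def test_banding_width_must_be_below_period(self):
        with pytest.raises(WallModelError):
            BandingSpec("Mn", band_width=1200.0, band_period=1000.0,
                        amplitude_profile={"ICL": 0.5})

    def test_negative_concentration_rejected(self):
        with pytest.raises(WallModelError):
            LayerSpec("ICL", 1000.0, {"Ca": -0.1})


class TestConcentrationField:
    def test_mn_at_gc_center_has_no_banding(self, ytt_model):
        lo, hi = ytt_model.layer_interval("GC")
        value = concentration_profile(ytt_model, "Mn",
                                      np.array([(lo + hi) / 2]))
        assert value[0] == pytest.approx(0.05)

    def test_ca_between_icl_bands_is_layer_scale(self, ytt_model):
        # ICL Ca band centres sit at 150, 1150, 2150 nm; 1500 nm is clear
        value = concentration_profile(ytt_model, "Ca", np.array([1500.0]))
        assert value[0] == pytest.approx(1.2)

    def test_positions_outside_wall_rejected(self, ytt_model):
        with pytest.raises(WallModelError):
            concentration_profile(ytt_model, "Ca", np.array([-1.0]))
        with pytest.raises(WallModelError):
            concentration_profile(ytt_model, "Ca", np.array([15000.1]))

    def test_field_non_negative_everywhere(self, ytt_model):
        x = np.linspace(0.0, ytt_model.total_thickness, 20001)
        for el in ytt_model.elements:
            assert concentration_profile(ytt_model, el, x).min() >= 0.0

    def test_mn_layer_means_match_closed_form(self, ytt_model):
        """Numeric layer means agree with the analytic piecewise+band form.

        For a raised-cosine band of width w, amplitude a and linear
        taper f(x), the band integral is a * f(centre) * w / 2 (the
        taper's odd part integrates to zero over the symmetric bump).
        """
        banding = next(b for b in ytt_model.bandings if b.element == "Mn")
        w, period = banding.band_width, banding.band_period
        poz_lo, poz_hi = ytt_model.layer_interval("POZ")
        total = ytt_model.total_thickness

        def closed_form_mean(layer):
            lo, hi = ytt_model.layer_interval(layer)
            scale = dict(zip(("ICL", "POZ", "OCL", "GC"),
                             [l.concentration_scale["Mn"]
                              for l in ytt_model.layers]))[layer]
            amp = banding.amplitude_profile.get(layer, 0.0)
            if amp == 0.0:
                return scale
            inner = hi <= poz_lo
            n_bands = int((hi - lo - w) // period) + 1
            ks = np.arange(n_bands)
            centres = (lo + w / 2 + ks * period) if inner \
                else (hi - w / 2 - ks * period)
            span = poz_lo if inner else total - poz_hi
            d = (poz_lo - centres) if inner else (centres - poz_hi)
            taper = 1.0 - (1.0 - banding.taper_distal) * d / span
            integral = scale * ((hi - lo) + amp * np.sum(taper) * w / 2)
            return integral / (hi - lo)

        for layer in ("ICL", "OCL", "GC"):
            lo, hi = ytt_model.layer_interval(layer)
            x = np.linspace(lo, hi, 200001)
            numeric = np.trapezoid(
                concentration_profile(ytt_model, "Mn", x), x) / (hi - lo)
            assert numeric == pytest.approx(closed_form_mean(layer),
                                            rel=1e-3)

    def test_mn_icl_to_ocl_mean_ratio_near_two(self, ytt_model):
        means = []
        for layer in ("ICL", "OCL"):
            lo, hi = ytt_model.layer_interval(layer)
            x = np.linspace(lo, hi, 100001)
            means.append(np.trapezoid(
                concentration_profile(ytt_model, "Mn", x), x) / (hi - lo))
        assert means[0] / means[1] == pytest.approx(2.0, rel=0.05)


@pytest.fixture(scope="module")
def tiny_model():
    """A thin wall for cheap multi-seed rendering."""
    layers = [
        LayerSpec("ICL", 600.0, {"Ca": 1.2, "Mn": 0.4}),
        LayerSpec("POZ", 400.0, {"Ca": 1.0, "Mn": 1.0}),
        LayerSpec("OCL", 900.0, {"Ca": 1.5, "Mn": 0.2}),
        LayerSpec("GC", 500.0, {"Ca": 1.5, "Mn": 0.05}),
    ]
    return WallModel(layers=layers, bulk_scale={"Ca": 500.0, "Mn": 40.0})


@pytest.fixture(scope="module")
def tiny_acq(tiny_model):
    return default_acquisition(tiny_model, height=8, seed=7)


class TestRendering:
    def test_maps_are_integer_and_non_negative(self, tiny_model, tiny_acq):
        stack = render_element_maps(tiny_model, tiny_acq)
        for line in stack.lines:
            counts = stack[line].counts
            assert np.issubdtype(counts.dtype, np.integer)
            assert counts.min() >= 0

    def test_rendering_is_deterministic_per_seed(self, tiny_model, tiny_acq):
        a = render_element_maps(tiny_model, tiny_acq)
        b = render_element_maps(tiny_model, tiny_acq)
        assert a == b
        other = AcquisitionSpec(**{**tiny_acq.__dict__, "seed": 8})
        c = render_element_maps(tiny_model, other)
        assert not np.array_equal(a["Ca"].counts, c["Ca"].counts)

    def test_zero_bulk_scale_gives_all_zero_map(self, tiny_model, tiny_acq):
        from dataclasses import replace
        model = replace(tiny_model, bulk_scale={"Ca": 0.0})
        stack = render_element_maps(model, tiny_acq)
        assert stack["Ca"].counts.sum() == 0

    def test_poisson_mean_and_dispersion_over_seeds(self, tiny_model,
                                                    tiny_acq):
        """Empirical mean tracks the expectation and variance ~ mean."""
        expected = expected_element_maps(tiny_model, tiny_acq)["Mn"]
        draws = []
        for seed in range(200):
            acq = AcquisitionSpec(**{**tiny_acq.__dict__, "seed": seed})
            draws.append(render_element_maps(tiny_model, acq)["Mn"].counts)
        draws = np.asarray(draws, dtype=float)
        mean = draws.mean(axis=0)
        # Monte-Carlo error of the mean is sqrt(mu/200) per pixel
        z = (mean - expected) / np.sqrt(expected / 200)
        assert np.abs(z.mean()) < 0.5
        assert np.abs(z).max() < 5.0
        dispersion = draws.var(axis=0, ddof=1) / expected
        assert 0.9 <= dispersion.mean() <= 1.1

    def test_expected_totals_stable_under_pixel_refinement(self, tiny_model):
        coarse = expected_bulk_counts(
            tiny_model, default_acquisition(tiny_model, pixel_size=60.0))
        fine = expected_bulk_counts(
            tiny_model, default_acquisition(tiny_model, pixel_size=15.0))
        for el in coarse:
            assert coarse[el] == pytest.approx(fine[el], rel=5e-3)

    def test_bulk_counts_only_nonzero_for_present_elements(self, tiny_model):
        from dataclasses import replace
        model = replace(tiny_model, bulk_scale={"Ca": 500.0, "Mn": 0.0})
        counts = render_bulk_counts(model, default_acquisition(model))
        assert counts["Ca"] > 0
        assert counts["Mn"] == 0

    def test_expected_bulk_counts_linear_in_dwell(self, tiny_model):
        a1 = default_acquisition(tiny_model, dwell_time=3.0)
        a2 = default_acquisition(tiny_model, dwell_time=6.0)
        e1 = expected_bulk_counts(tiny_model, a1)
        e2 = expected_bulk_counts(tiny_model, a2)
        for el in e1:
            assert e2[el] == pytest.approx(2.0 * e1[el])

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(WallModelError):
            AcquisitionSpec(dwell_time=0.0)
        with pytest.raises(WallModelError):
            AcquisitionSpec(pixel_size=-1.0)


class TestBulkPresetCalibration:
    def test_expected_ytt_over_modern_bulk_mn_is_calibrated(
            self, ytt_model, modern_model):
        ey = expected_bulk_counts(ytt_model, default_acquisition(ytt_model))
        em = expected_bulk_counts(modern_model,
                                  default_acquisition(modern_model))
        assert ey["Mn"] / em["Mn"] == pytest.approx(YTT_TO_MODERN_BULK_MN,
                                                    rel=1e-6)

    def test_modern_wall_mean_mn_concentration(self, modern_model):
        # relative fields are POZ-normalised in both presets
        assert _mean_concentration(modern_model, "Mn") > 0
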