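"""Thickness profiles, ridge metrics, feature aggregation, age trends."""

import numpy as np
import pandas as pd
import pytest

from dermatomics import morphometrics, skeleton, synthetic
from dermatomics.morphometrics import (
    aggregate_stats,
    fit_age_trend,
    ridge_metrics,
    slice_features,
    thickness_profile,
)
from dermatomics.skeleton import BoundaryIndex


def _analyze_truth(truth, min_path=500):
    tb = BoundaryIndex(truth.tissue_mask)
    g = skeleton.analyze_component(truth.epidermis_mask, tb, min_path)
    eb = BoundaryIndex(truth.epidermis_mask, scope="epidermal-boundary")
    return g, eb


class TestThicknessProfile:
    def test_centered_midline_in_band(self):
        band = np.zeros((41, 200), bool)
        band[10:31, :] = True  # 21 rows tall
        midline = np.stack([np.full(200, 20), np.arange(200)], axis=1)
        prof = thickness_profile(midline, BoundaryIndex(band))
        interior = prof.values[5:-5]
        assert np.all(np.abs(interior - 20) <= 2)

    def test_pixel_adjacent_to_boundary(self):
        band = np.zeros((10, 10), bool)
        band[2:8, 2:8] = True
        prof = thickness_profile(np.array([[3, 3]]), BoundaryIndex(band))
        assert prof.values[0] == 2.0  # distance 1, doubled

    def test_annulus_constant_profile(self):
        yy, xx = np.mgrid[:201, :201]
        r = np.hypot(yy - 100, xx - 100)
        annulus = (r >= 60) & (r <= 80)
        theta = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        mid = np.stack(
            [np.round(100 + 70 * np.sin(theta)), np.round(100 + 70 * np.cos(theta))],
            axis=1,
        )
        prof = thickness_profile(mid, BoundaryIndex(annulus))
        cv = prof.values.std() / prof.values.mean()
        assert cv < 0.10


class TestRidgeMetrics:
    def test_phantom_ridge_length(self, he_phantom):
        _, truth = he_phantom
        g, eb = _analyze_truth(truth)
        mid = g.midline_pixels()
        metrics = [ridge_metrics(r, g, mid, eb) for r in g.valid_ridges]
        assert len(metrics) == truth.params["n_ridges"]
        expected = truth.params["ridge_length"] + truth.params["band_thickness"] / 2
        med = np.median([m.length for m in metrics])
        assert abs(med - expected) / expected < 0.15

    def test_blunt_ridge_dilation_near_one(self):
        spec = synthetic.SkinPhantomSpec(
            band_thickness=24, ridge_base_width=24, ridge_end_width=24, seed=3
        )
        _, truth = synthetic.render_he_phantom(spec)
        g, eb = _analyze_truth(truth)
        mid = g.midline_pixels()
        dil = [ridge_metrics(r, g, mid, eb).dilation_factor for r in g.valid_ridges]
        assert abs(np.median(dil) - 1.0) < 0.2

    def test_tapering_ridge_dilation(self):
        spec = synthetic.SkinPhantomSpec(
            band_thickness=28, ridge_base_width=28, ridge_end_width=14, seed=3
        )
        _, truth = synthetic.render_he_phantom(spec)
        g, eb = _analyze_truth(truth)
        mid = g.midline_pixels()
        dil = np.median(
            [ridge_metrics(r, g, mid, eb).dilation_factor for r in g.valid_ridges]
        )
        assert abs(dil - 0.5) / 0.5 < 0.2


class TestSliceFeatures:
    def test_density_and_area_per_length(self, he_phantom):
        _, truth = he_phantom
        tb = BoundaryIndex(truth.tissue_mask)
        g = skeleton.analyze_component(truth.epidermis_mask, tb, 500)
        rec = slice_features([(g, truth.epidermis_mask)], "ACC1", 0)
        f = rec.features
        assert f["ridge_density"] == f["ridge_count"] / f["epidermal_length_px"]
        assert f["area_per_length"] == pytest.approx(
            truth.epidermis_mask.sum() / f["epidermal_length_px"]
        )
        assert f["ridge_count"] == truth.params["n_ridges"]

    def test_no_accepted_components_returns_none(self):
        m = np.zeros((20, 60), bool)
        m[8:12, 5:55] = True  # midline far below 500 px
        tb = BoundaryIndex(np.ones_like(m))
        g = skeleton.analyze_component(m, tb, 500)
        assert slice_features([(g, m)], "ACC", 0) is None

    def test_aggregates_match_order_statistics(self):
        vals = np.array([10.0, 10.0, 20.0, 20.0])
        s = aggregate_stats(vals)
        assert s["median"] == 15.0
        assert s["iqr"] == s["p75"] - s["p25"]
        assert s["range"] == 10.0
        assert s["mean"] == 15.0

    def test_aggregate_identities_hypothesis(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(
            st.lists(
                st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=40
            )
        )
        def check(values):
            s = aggregate_stats(np.array(values))
            assert s["iqr"] == pytest.approx(s["p75"] - s["p25"], abs=1e-6)
            assert s["p5"] <= s["p25"] <= s["median"] <= s["p75"] <= s["p95"]
            assert s["range"] >= 0 and s["std"] >= 0
            assert min(values) <= s["mean"] <= max(values)

        check()

    def test_aggregates_against_brute_force(self, rng):
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 50))
            s = aggregate_stats(v)
            sv = np.sort(v)
            assert s["mean"] == pytest.approx(sv.sum() / len(sv))
            assert s["median"] == pytest.approx(np.percentile(sv, 50))
            assert s["range"] == pytest.approx(sv[-1] - sv[0])
            assert s["iqr"] == pytest.approx(
                np.percentile(sv, 75) - np.percentile(sv, 25)
            )


class TestScalingInvariance:
    def test_double_scale_doubles_lengths_halves_density(self):
        def measure(spec):
            _, truth = synthetic.render_he_phantom(spec)
            tb = BoundaryIndex(truth.tissue_mask)
            g = skeleton.analyze_component(truth.epidermis_mask, tb, 500)
            eb = BoundaryIndex(truth.epidermis_mask, scope="epidermal-boundary")
            mid = g.midline_pixels()
            ms = [ridge_metrics(r, g, mid, eb) for r in g.valid_ridges]
            return (
                len(mid),
                np.median([m.length for m in ms]),
                np.median([m.dilation_factor for m in ms]),
                len(ms) / len(mid),
            )

        base = dict(n_ridges=4, seed=2)
        spec1 = synthetic.SkinPhantomSpec(**base)
        spec2 = synthetic.SkinPhantomSpec(
            **base,
            shape=(640, 2800), band_top=80, band_thickness=48,
            ridge_length=160, ridge_base_width=48, ridge_end_width=32,
            edge_margin=400,
        )
        L1, len1, dil1, dens1 = measure(spec1)
        L2, len2, dil2, dens2 = measure(spec2)
        assert L2 / L1 == pytest.approx(2.0, rel=0.05)
        assert len2 / len1 == pytest.approx(2.0, rel=0.10)
        assert dil2 == pytest.approx(dil1, rel=0.15)  # scale-invariant
        assert dens2 / dens1 == pytest.approx(0.5, rel=0.10)


class TestFitAgeTrend:
    def test_exact_line(self):
        ages = np.arange(20, 80, 5.0)
        df = pd.DataFrame({"age": ages, "f": 2 * ages + 1})
        fit = fit_age_trend(df, "f")
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-12
        assert fit.conf_band is not None and len(fit.conf_band) == 50

    def test_constant_feature_degenerate(self):
        df = pd.DataFrame({"age": [20.0, 40, 60, 80], "f": [3.0, 3, 3, 3]})
        fit = fit_age_trend(df, "f")
        assert fit.degenerate and fit.slope == 0.0 and fit.p_value == 1.0

    def test_too_few_ages(self):
        df = pd.DataFrame({"age": [20.0, 20, 30], "f": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="distinct ages"):
            fit_age_trend(df, "f")

    def test_null_calibration_smoke(self):
        # full 1000-replicate calibration lives in the acceptance suite
        rng = np.random.default_rng(99)
        rej = sum(
            fit_age_trend(
                pd.DataFrame(
                    {"age": rng.uniform(20, 80, 100), "f": rng.normal(0, 1, 100)}
                ),
                "f",
            ).p_value
            < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rej / 200 <= 0.10
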