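"""Water-column feature detection: MLD, nitracline, euphotic depth,
subsurface extrema, transition depth, light/dark comparison."""

import numpy as np
import pytest
from scipy import stats

from n15rates.profiles import (
    InsufficientOverlapError,
    InvalidOpticsError,
    StationProfile,
    attenuation_coefficient,
    detect_features,
    euphotic_depth,
    extremum_layers,
    mixed_layer_depth,
    nitracline,
    ols_r2,
    paired_light_dark_test,
    transition_depth,
)


class TestMixedLayerDepth:
    def test_linear_interpolation_between_bottles(self):
        assert mixed_layer_depth([0, 40, 60], [28.0, 28.0, 26.0]) == \
            pytest.approx(48.0)

    def test_isothermal_profile_has_no_mld(self):
        assert mixed_layer_depth([0, 50, 100], [25.0, 25.0, 25.0]) is None

    def test_threshold_at_exact_bottle_depth(self):
        assert mixed_layer_depth([0, 30, 60], [28.0, 27.2, 25.0]) == \
            pytest.approx(30.0)

    def test_custom_threshold(self):
        assert mixed_layer_depth([0, 40, 60], [28.0, 28.0, 26.0],
                                 delta_t=1.0) == pytest.approx(50.0)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            mixed_layer_depth([0], [28.0])


class TestNitracline:
    def test_logistic_profile_midpoint_near_inflection(self):
        z = np.arange(0, 201, 5.0)
        no3 = 6.0 / (1.0 + np.exp(-(z - 70.0) / 8.0))
        res = nitracline(z, no3)
        assert res is not None
        assert abs(res.midpoint_m - 70.0) <= 2.5
        assert res.top_m < 70.0 < res.bottom_m

    def test_uniform_high_no3_has_no_nitracline(self):
        # well-mixed eutrophic coastal water: nutrient replete at all depths
        z = np.arange(0, 101, 10.0)
        assert nitracline(z, np.full(z.size, 8.0)) is None

    def test_linear_increase_spans_profile(self):
        z = np.arange(0, 101, 10.0)
        res = nitracline(z, 0.05 * z)
        assert res.top_m == 0.0 and res.bottom_m == 100.0
        assert res.midpoint_m == pytest.approx(50.0)

    def test_translation_equivariance(self):
        z = np.arange(0, 201, 5.0)
        no3 = 6.0 / (1.0 + np.exp(-(z - 70.0) / 8.0))
        base = nitracline(z, no3).midpoint_m
        no3_shifted = 6.0 / (1.0 + np.exp(-(z - 95.0) / 8.0))
        shifted = nitracline(z, no3_shifted).midpoint_m
        assert shifted - base == pytest.approx(25.0, abs=2.5)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            nitracline([0, 10], [0.1, 1.0])


class TestEuphoticDepth:
    def test_printed_k_value(self):
        # k = 0.06 per m -> 0.1% sPAR depth of ~115 m
        k, z = euphotic_depth(k=0.06)
        assert z == pytest.approx(115.1, abs=0.1)

    def test_fraction_one_is_surface(self):
        _, z = euphotic_depth(k=0.06, fraction=1.0)
        assert z == 0.0

    def test_exact_exponential_recovery(self):
        depth = np.arange(0, 201, 5.0)
        par = 100.0 * np.exp(-0.05 * depth)
        k, z = euphotic_depth(depth=depth, par=par)
        assert k == pytest.approx(0.05, rel=1e-9)
        assert z == pytest.approx(np.log(1000.0) / 0.05, rel=1e-9)

    def test_strictly_decreasing_in_k(self):
        zs = [euphotic_depth(k=k)[1] for k in [0.04, 0.05, 0.06, 0.08]]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_nondecreasing_par_invalid(self):
        depth = np.arange(0, 50, 5.0)
        with pytest.raises(InvalidOpticsError):
            attenuation_coefficient(depth, np.full(depth.size, 10.0))


class TestExtremumLayers:
    @staticmethod
    def _profile(**kwargs):
        z = np.arange(0, 201, 5.0)
        return StationProfile(depth_m=z, **kwargs), z

    def test_gaussian_dcm_recovered(self):
        profile, z = self._profile(
            chl_fluor=0.05 + np.exp(-((np.arange(0, 201, 5.0) - 75.0)
                                      / 15.0) ** 2))
        layers = extremum_layers(profile)
        assert layers.dcm_depth_m == pytest.approx(75.0)
        assert not layers.dcm_boundary

    def test_monotone_series_flagged_boundary(self):
        profile, z = self._profile(no2=np.linspace(1.0, 50.0, 41))
        layers = extremum_layers(profile)
        assert layers.pnm_depth_m == 200.0
        assert layers.pnm_boundary

    def test_flat_series_has_no_extremum(self):
        profile, _ = self._profile(no2=np.full(41, 5.0))
        assert extremum_layers(profile).pnm_depth_m is None

    def test_zero_sio4_depths_excluded_from_ratio(self):
        z = np.arange(0, 201, 5.0)
        sio4 = np.ones(z.size)
        sio4[10] = 0.0
        no3 = np.ones(z.size)
        no3[10] = 100.0  # would dominate if not excluded
        no3[20] = 2.0
        profile = StationProfile(depth_m=z, no3=no3, sio4=sio4)
        layers = extremum_layers(profile)
        assert layers.no3_si_ratio_max_depth_m == pytest.approx(z[20])

    def test_ties_broken_shallow(self):
        z = np.arange(0, 51, 10.0)
        chl = np.array([1.0, 5.0, 3.0, 5.0, 1.0, 0.5])
        profile = StationProfile(depth_m=z, chl_fluor=chl)
        assert extremum_layers(profile).dcm_depth_m == pytest.approx(10.0)


class TestTransitionDepth:
    def test_unimodal_crossover_recovered(self):
        z = np.arange(0, 201, 5.0)
        uptake = 25.0 * np.exp(-((z - 25.0) / 30.0) ** 2)
        nitrif = 18.0 * np.exp(-((z - 95.0) / 30.0) ** 2)
        # analytic crossing of the two curves
        from scipy.optimize import brentq
        z_true = brentq(lambda x: 18.0 * np.exp(-((x - 95.0) / 30.0) ** 2)
                        - 25.0 * np.exp(-((x - 25.0) / 30.0) ** 2), 25, 95)
        res = transition_depth(z, uptake, z, nitrif)
        assert res.status == "crossover"
        assert res.depth_m == pytest.approx(z_true, abs=2.5)

    def test_surface_dominated_when_nitrification_exceeds_everywhere(self):
        z = np.arange(0, 101, 10.0)
        res = transition_depth(z, np.full(z.size, 1.0), z,
                               np.full(z.size, 2.0))
        assert res.depth_m is None
        assert res.status == "surface_dominated"

    def test_transient_flips_do_not_count(self):
        # co-occurring comparable rates: alternating dominance never
        # persists two samples
        z = np.arange(0, 101, 10.0)
        uptake = np.full(z.size, 1.0)
        nitrif = np.where(np.arange(z.size) % 2 == 0, 0.9, 1.1)
        res = transition_depth(z, uptake, z, nitrif)
        assert res.depth_m is None
        assert res.status == "no_crossover"

    def test_different_grids_are_interpolated(self):
        zu = np.arange(0, 201, 5.0)
        zn = np.arange(0, 201, 10.0)
        uptake = 25.0 * np.exp(-((zu - 25.0) / 30.0) ** 2)
        nitrif = 18.0 * np.exp(-((zn - 95.0) / 30.0) ** 2)
        res = transition_depth(zu, uptake, zn, nitrif)
        assert res.status == "crossover"
        assert 40.0 < res.depth_m < 90.0

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientOverlapError):
            transition_depth([0, 10, 20], [1, 1, 1], [100, 110], [2, 2])


class TestLightDarkTest:
    def test_identical_groups(self):
        res = paired_light_dark_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_closed_form_two_sample_t(self):
        a = np.array([2.1, 2.5, 2.3, 2.2])
        b = np.array([1.1, 1.4, 1.0, 1.3])
        res = paired_light_dark_test(a, b, paired=False)
        expected = stats.ttest_ind(a, b)
        # closed form: t = (ma - mb)/sqrt(sp2 (1/na + 1/nb))
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) \
            / (a.size + b.size - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.p == pytest.approx(expected.pvalue, rel=1e-12)
        assert res.mean_difference == pytest.approx(a.mean() - b.mean())

    def test_paired_uses_depth_matching(self):
        light = [0.2, 0.5, 1.0, 2.0]
        dark = [0.5, 0.9, 1.6, 2.9]
        res = paired_light_dark_test(light, dark)
        assert res.paired
        expected = stats.ttest_rel(light, dark)
        assert res.t == pytest.approx(float(expected.statistic))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            paired_light_dark_test([1.0], [1.0, 2.0])


class TestProfileContainer:
    def test_depths_must_increase(self):
        with pytest.raises(ValueError):
            StationProfile(depth_m=[0, 10, 10], no3=[1, 2, 3])

    def test_series_alignment(self):
        with pytest.raises(ValueError):
            StationProfile(depth_m=[0, 10, 20], no3=[1, 2])

    def test_detect_features_within_profile_span(self):
        z = np.arange(0, 201, 5.0)
        temp = 28.0 - 12.0 * (1 - np.exp(-np.clip(z - 30, 0, None) / 60.0))
        par = 100.0 * np.exp(-0.06 * z)
        no3 = 6.0 / (1.0 + np.exp(-(z - 70.0) / 8.0))
        chl = 0.05 + np.exp(-((z - 75.0) / 15.0) ** 2)
        uptake = 25.0 * np.exp(-((z - 25.0) / 35.0) ** 2)
        nitrif = 18.0 * np.exp(-((z - 90.0) / 35.0) ** 2)
        profile = StationProfile(depth_m=z, temperature_C=temp, par=par,
                                 no3=no3, chl_fluor=chl,
                                 rates={"nh4_uptake": uptake,
                                        "nh4_oxidation": nitrif})
        f = detect_features(profile)
        for depth in [f.mld_m, f.nitracline_depth_m, f.euphotic_depth_m,
                      f.extrema.dcm_depth_m, f.transition.depth_m]:
            assert depth is not None
            assert z.min() <= depth <= z.max()

    def test_ols_r2_perfect_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, p = ols_r2(x, 2.0 * x + 1.0)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)
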