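"""Michaelis-Menten kinetics: forward model, fitting, affinity,
estimator comparison."""

import itertools

import numpy as np
import pytest

from n15rates.kinetics import (
    DEFAULT_KINETIC_LEVELS,
    EstimatorComparison,
    KineticSeries,
    MichaelisMentenModel,
    UnidentifiableDesignError,
    affinity,
    bulk_overestimation_factor,
    compare_estimators,
    fit_mm,
    mm_rate,
    rate_kinetic_at,
)
from n15rates.simulate import IncubationTruth, simulate_incubation


def grid_search_sse(s, r, vmax_grid, ks_grid):
    """Brute-force least-squares oracle on a (vmax, ks) lattice."""
    best = (np.inf, None, None)
    for v, k in itertools.product(vmax_grid, ks_grid):
        sse = float(np.sum((v * s / (k + s) - r) ** 2))
        if sse < best[0]:
            best = (sse, v, k)
    return best


class TestForwardModel:
    def test_half_saturation(self):
        assert mm_rate(22.0, 300.0, 300.0) == pytest.approx(11.0)

    def test_saturation_limit(self):
        assert mm_rate(22.0, 300.0, 1e12) == pytest.approx(22.0, rel=1e-9)

    def test_hand_evaluated(self):
        assert mm_rate(22.0, 300.0, 2000.0) == pytest.approx(19.130, abs=1e-3)

    def test_monotone_concave(self):
        s = np.linspace(0.0, 5000.0, 200)
        r = mm_rate(10.0, 100.0, s)
        d1 = np.diff(r)
        assert np.all(d1 > 0)
        assert np.all(np.diff(d1) < 0)

    def test_bounded_by_vmax_and_initial_slope_is_alpha(self):
        vmax, ks = 7.0, 250.0
        s = np.linspace(0, 1e4, 100)[1:]
        assert np.all(mm_rate(vmax, ks, s) < vmax)
        eps = 1e-7
        slope = mm_rate(vmax, ks, eps) / eps
        assert slope == pytest.approx(vmax / ks, rel=1e-6)


class TestFitting:
    def test_exact_recovery_noise_free(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        fit = MichaelisMentenModel(s, mm_rate(22.0, 300.0, s)).fit()
        assert fit.converged
        assert fit.vmax == pytest.approx(22.0, rel=1e-6)
        assert fit.ks == pytest.approx(300.0, rel=1e-6)
        assert fit.alpha == pytest.approx(22.0 / 300.0, rel=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        s = np.array([10.0, 100.0, 500.0, 2000.0])
        r = mm_rate(15.0, 400.0, s) * (1 + rng.normal(0, 0.05, 4))
        fit = MichaelisMentenModel(s, r).fit()
        sse_fit = fit.residual_norm**2
        vgrid = np.linspace(0.5 * fit.vmax, 1.5 * fit.vmax, 201)
        kgrid = np.linspace(0.5 * fit.ks, 1.5 * fit.ks, 201)
        sse_grid, v_best, k_best = grid_search_sse(s, r, vgrid, kgrid)
        assert sse_fit <= sse_grid + 1e-9
        assert fit.vmax == pytest.approx(v_best, abs=vgrid[1] - vgrid[0])
        assert fit.ks == pytest.approx(k_best, abs=kgrid[1] - kgrid[0])

    def test_median_bias_under_5pct_noise(self, rng):
        vbias, kbias = [], []
        levels = np.repeat(np.array(DEFAULT_KINETIC_LEVELS) + 20.0, 2)
        for _ in range(200):
            r = mm_rate(22.0, 300.0, levels) * (1 + rng.normal(0, 0.05,
                                                               levels.size))
            fit = MichaelisMentenModel(levels, r).fit()
            vbias.append(abs(fit.vmax / 22.0 - 1.0))
            kbias.append(abs(fit.ks / 300.0 - 1.0))
        assert np.median(vbias) < 0.10
        assert np.median(kbias) < 0.10

    def test_invariant_to_point_order_and_duplication(self):
        s = np.array([10.0, 100.0, 500.0, 2000.0])
        r = mm_rate(22.0, 300.0, s) * np.array([1.02, 0.99, 1.01, 0.98])
        f1 = MichaelisMentenModel(s, r).fit()
        f2 = MichaelisMentenModel(s[::-1], r[::-1]).fit()
        f3 = MichaelisMentenModel(np.tile(s, 2), np.tile(r, 2)).fit()
        assert f2.vmax == pytest.approx(f1.vmax, rel=1e-8)
        assert f2.ks == pytest.approx(f1.ks, rel=1e-8)
        assert f3.vmax == pytest.approx(f1.vmax, rel=1e-6)
        assert f3.ks == pytest.approx(f1.ks, rel=1e-6)

    def test_poor_design_inflates_ks_uncertainty(self, rng):
        # max substrate far below Ks: Ks only weakly identified
        good = np.repeat(np.array([10.0, 100.0, 500.0, 2000.0]), 2)
        poor = np.repeat(np.array([5.0, 10.0, 20.0, 40.0]), 2)
        ratios = []
        for _ in range(20):
            noise_g = 1 + rng.normal(0, 0.03, good.size)
            noise_p = 1 + rng.normal(0, 0.03, poor.size)
            fg = MichaelisMentenModel(good, mm_rate(22, 300, good) * noise_g).fit()
            fp = MichaelisMentenModel(poor, mm_rate(22, 300, poor) * noise_p).fit()
            ratios.append((fp.ks_se / fp.ks) / (fg.ks_se / fg.ks))
        assert np.median(ratios) > 1.0

    def test_unidentifiable_design(self):
        with pytest.raises(UnidentifiableDesignError):
            MichaelisMentenModel([100.0, 100.0, 100.0], [1.0, 1.1, 0.9])

    def test_from_series_and_summary(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        series = KineticSeries(s_total=s, rate=mm_rate(22.0, 300.0, s))
        fit = fit_mm(series)
        text = fit.summary()
        assert "Vmax" in text and "Ks" in text and "alpha" in text


class TestAffinity:
    def test_alpha_is_vmax_over_ks(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        fit = MichaelisMentenModel(s, mm_rate(10.0, 100.0, s)).fit()
        assert affinity(fit) == pytest.approx(0.1, rel=1e-6)

    def test_scaling_vmax_doubles_alpha(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        f1 = MichaelisMentenModel(s, mm_rate(10.0, 100.0, s)).fit()
        f2 = MichaelisMentenModel(s, mm_rate(20.0, 100.0, s)).fit()
        assert affinity(f2) == pytest.approx(2 * affinity(f1), rel=1e-6)

    def test_comparison_ranks_processes(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        phyto = MichaelisMentenModel(s, mm_rate(20.0, 100.0, s)).fit()
        nitrifier = MichaelisMentenModel(s, mm_rate(10.0, 200.0, s)).fit()
        assert affinity(phyto) > affinity(nitrifier)


class TestRateKineticAt:
    def test_zero_ambient(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        fit = MichaelisMentenModel(s, mm_rate(22.0, 300.0, s)).fit()
        assert rate_kinetic_at(fit, 0.0).value == 0.0

    def test_hand_evaluated(self):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        fit = MichaelisMentenModel(s, mm_rate(22.0, 300.0, s)).fit()
        est = rate_kinetic_at(fit, 20.0)
        assert est.method == "kinetic"
        assert est.value == pytest.approx(1.375, rel=1e-5)
        assert est.value == pytest.approx(fit.predict(20.0))


class TestEstimatorComparison:
    @staticmethod
    def _truth_fit(truth):
        s = np.array(DEFAULT_KINETIC_LEVELS)
        return MichaelisMentenModel(
            s, mm_rate(truth.vmax, truth.ks, s)).fit()

    def test_no_tracer_factor_is_one(self):
        truth = IncubationTruth(ks=1000.0)
        recs, _ = simulate_incubation(truth, spike_conc=0.0, duration_h=12.0,
                                      replicates=1, noise=False, light="dark")
        # unlabelled control: add an infinitesimal label so f15 is defined
        rec = recs[0]
        rec.substrate_atom_frac = truth.substrate_atom_frac(1e-9)
        comp = compare_estimators(rec, self._truth_fit(truth))
        assert comp.overestimation_factor == pytest.approx(1.0, rel=1e-6)

    def test_closed_form_factor_reproduced_by_simulation(self):
        # Ci = Ct = 20, Ks = 1000: factor (Ci+Ct)(Ks+Ci)/[Ci(Ks+Ci+Ct)]
        truth = IncubationTruth(ks=1000.0, ambient_substrate_conc=20.0)
        recs, ground = simulate_incubation(truth, spike_conc=20.0,
                                           duration_h=12.0, replicates=1,
                                           noise=False, light="dark")
        comp = compare_estimators(recs[0], self._truth_fit(truth))
        expected = bulk_overestimation_factor(20.0, 20.0, 1000.0)
        assert expected == pytest.approx(1.9615, abs=1e-4)
        assert comp.overestimation_factor == pytest.approx(expected, rel=1e-3)
        assert comp.r_in_situ == pytest.approx(ground.rate_ambient, rel=0.05)
        assert comp.first_order_ok

    def test_factor_decreases_with_ambient_concentration(self):
        truth_template = dict(ks=1000.0)
        factors = []
        for ci in [5.0, 20.0, 80.0, 250.0, 650.0]:
            truth = IncubationTruth(ambient_substrate_conc=ci,
                                    **truth_template)
            recs, _ = simulate_incubation(truth, spike_conc=50.0,
                                          duration_h=12.0, replicates=1,
                                          noise=False, light="dark")
            comp = compare_estimators(recs[0], self._truth_fit(truth))
            factors.append(comp.overestimation_factor)
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_flags_saturated_design(self):
        truth = IncubationTruth(ks=30.0)
        recs, _ = simulate_incubation(truth, spike_conc=20.0, duration_h=12.0,
                                      replicates=1, noise=False, light="dark")
        comp = compare_estimators(recs[0], self._truth_fit(truth))
        assert not comp.first_order_ok


class TestClosedFormFactor:
    def test_limits(self):
        assert bulk_overestimation_factor(20.0, 0.0, 1000.0) == pytest.approx(1.0)
        assert bulk_overestimation_factor(20.0, 20.0, 1000.0) == pytest.approx(
            1.9615, abs=1e-4)

    def test_monotone_in_ci(self):
        cis = np.linspace(5, 650, 50)
        f = [bulk_overestimation_factor(ci, 50.0, 1000.0) for ci in cis]
        assert all(a > b for a, b in zip(f, f[1:]))
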