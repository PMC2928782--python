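"""FRAP signal normalization, relaxation fitting and rate extraction.

Oracles: direct evaluation of the compositional transform, an
independent 2x2 eigensolver for the relaxation rate, finite differences
for the error-propagation Jacobian, and simulation round-trips.
"""

import numpy as np
import pandas as pd
import pytest

from cytolink import frap, synth


def make_trace(**kw):
    return synth.simulate_frap_trace(synth.FrapTruth(**kw))


class TestNormalizeSignals:
    def test_direct_evaluation(self):
        trace = frap.FrapTrace(
            t=[0.0, 1.0], S_cyt=[2.0, 2.0], S_nuc=[8.0, 8.0],
            V_cyt=4.0, V_nuc=1.0, c_cyt=1.0, c_nuc=1.0, bleach_index=0,
        )
        cyt, nuc = frap.normalize_signals(trace)
        np.testing.assert_allclose(cyt, 0.5)
        np.testing.assert_allclose(nuc, 0.5)

    def test_common_factor_cancels_and_sums_to_one(self):
        trace = make_trace(noise_sd=0.0)
        cyt, nuc = frap.normalize_signals(trace)
        scaled = frap.FrapTrace(
            t=trace.t, S_cyt=7.3 * trace.S_cyt, S_nuc=7.3 * trace.S_nuc,
            V_cyt=trace.V_cyt, V_nuc=trace.V_nuc, c_cyt=trace.c_cyt,
            c_nuc=trace.c_nuc, bleach_index=trace.bleach_index,
        )
        cyt2, nuc2 = frap.normalize_signals(scaled)
        np.testing.assert_allclose(cyt, cyt2, rtol=1e-14)
        np.testing.assert_allclose(cyt + nuc, 1.0, rtol=1e-14)


class TestFitRelaxation:
    def test_noiseless_rate_matches_independent_eigensolver(self):
        truth = synth.FrapTruth(noise_sd=0.0)
        M = frap.transport_matrix(
            truth.alpha_imp, truth.alpha_exp, truth.V_cyt, truth.V_nuc
        )
        lam2 = float(-np.linalg.eigvals(M).min())
        fit = frap.fit_trace(synth.simulate_frap_trace(truth))
        assert fit.a1 == pytest.approx(lam2, rel=1e-6)

    @pytest.mark.parametrize("epsilon,drift", [(0.001, 0.0), (0.0, 0.002), (0.002, 8e-5)])
    def test_invariance_to_bleaching_and_scaling(self, epsilon, drift):
        base = frap.fit_trace(make_trace(epsilon=0.0, drift=0.0, noise_sd=0.0))
        pert = frap.fit_trace(make_trace(epsilon=epsilon, drift=drift, noise_sd=0.0))
        assert pert.a1 == pytest.approx(base.a1, rel=1e-6)

    def test_flat_trace_flagged(self):
        t = np.arange(20.0)
        y_cyt = np.full(20, 0.6)
        y_nuc = np.full(20, 0.4)
        fit = frap.fit_relaxation(y_cyt, y_nuc, 2.0, 1.0, t, bleach_index=5)
        assert "no_recovery" in fit.flags

    def test_noisy_recovery_median_error_below_5pct(self):
        truth0 = synth.FrapTruth()
        lam2 = truth0.alpha_imp / truth0.V_cyt + truth0.alpha_exp / truth0.V_nuc
        errs = []
        for seed in range(100):
            fit = frap.fit_trace(make_trace(noise_sd=0.02, seed=seed))
            errs.append(abs(fit.a1 - lam2) / lam2)
        assert np.median(errs) < 0.05


class TestExtractRates:
    def test_symmetric_cell_reduction(self):
        fit = frap.RelaxationFit(a0=1.0, a1=0.01, a2=0.0, cov=None, chi2=0.0)
        r = frap.extract_rates(fit, V_cyt=500.0, V_nuc=500.0, c_cyt=2.0, c_nuc=2.0)
        assert r.alpha_imp == pytest.approx(0.01 * 500 / 2)
        assert r.alpha_exp == pytest.approx(0.01 * 500 / 2)

    @pytest.mark.parametrize("k_mode", frap.K_MODES)
    def test_round_trip_under_all_normalizations(self, k_mode):
        truth = synth.FrapTruth(
            alpha_imp=0.02, alpha_exp=0.05, c_cyt=1.0, K_mode=k_mode, noise_sd=0.0
        )
        trace = synth.simulate_frap_trace(truth)
        fit = frap.fit_trace(trace)
        r = frap.extract_rates(
            fit, truth.V_cyt, truth.V_nuc, truth.c_cyt, truth.c_nuc, k_mode=k_mode
        )
        assert r.alpha_imp == pytest.approx(0.02, rel=1e-6)
        assert r.alpha_exp == pytest.approx(0.05, rel=1e-6)

    def test_equal_currents_identity(self, rng):
        for _ in range(20):
            vc, vn, cc, cn, a1 = rng.uniform(0.1, 10, 5)
            fit = frap.RelaxationFit(a0=1, a1=a1, a2=0, cov=None, chi2=0)
            r = frap.extract_rates(fit, vc, vn, cc, cn, k_mode="v_nuc")
            assert r.alpha_imp * cc == pytest.approx(r.alpha_exp * cn, rel=1e-10)

    def test_nonpositive_rate_rejected(self):
        fit = frap.RelaxationFit(a0=1, a1=-0.1, a2=0, cov=None, chi2=0)
        with pytest.raises(ValueError):
            frap.extract_rates(fit, 1, 1, 1, 1)


class TestPropagateErrors:
    def make_rates(self, k_mode="none"):
        fit = frap.RelaxationFit(a0=1, a1=0.0015, a2=0, cov=None, chi2=0)
        return frap.extract_rates(
            fit, V_cyt=1150.0, V_nuc=270.0, c_cyt=1.0, c_nuc=1.55, k_mode=k_mode
        )

    def test_zero_errors_give_zero_sigma(self):
        r = self.make_rates()
        si, se = frap.propagate_errors(r, rel_err_conc=0.0, rel_err_vol=0.0)
        assert si == 0.0 and se == 0.0

    def test_linearity_in_relative_errors(self):
        r = self.make_rates()
        s1 = frap.propagate_errors(r, 0.05, 0.05)
        s2 = frap.propagate_errors(r, 0.10, 0.10)
        assert s2[0] == pytest.approx(2 * s1[0], rel=1e-12)
        assert s2[1] == pytest.approx(2 * s1[1], rel=1e-12)

    @pytest.mark.parametrize("k_mode", frap.K_MODES)
    def test_matches_finite_difference_jacobian(self, k_mode):
        # independent oracle: numerically differentiate the rate formulas
        a1, vc, vn, cc, cn = 0.0015, 1150.0, 270.0, 1.0, 1.55
        A = 200.0
        rel = 0.10

        def alphas(a1, vc, vn, cc, cn, A):
            K = {"none": 1.0, "area": A, "v_nuc": vn, "v_cyt": vc}[k_mode]
            ai = a1 / (K * (1 / vc + (cc / cn) / vn))
            ae = a1 / (K * (1 / vn + (cn / cc) / vc))
            return np.array([ai, ae])

        x0 = np.array([a1, vc, vn, cc, cn, A])
        sig = np.array([0.0, rel * vc, rel * vn, rel * cc, rel * cn,
                        rel * A if k_mode == "area" else 0.0])
        var = np.zeros(2)
        for k in range(6):
            h = 1e-6 * max(abs(x0[k]), 1.0)
            xp, xm_ = x0.copy(), x0.copy()
            xp[k] += h
            xm_[k] -= h
            grad = (alphas(*xp) - alphas(*xm_)) / (2 * h)
            var += (grad * sig[k]) ** 2
        expected = np.sqrt(var)

        fit = frap.RelaxationFit(a0=1, a1=a1, a2=0, cov=None, chi2=0)
        r = frap.extract_rates(fit, vc, vn, cc, cn, k_mode=k_mode, A_nuc=A)
        si, se = frap.propagate_errors(r, rel_err_conc=rel, rel_err_vol=rel)
        assert si == pytest.approx(expected[0], rel=0.01)
        assert se == pytest.approx(expected[1], rel=0.01)


class TestCytoplasmicConcentration:
    def test_uniform_cell(self):
        assert frap.cytoplasmic_concentration(5.0, 2.0, 1.0, 2.0) == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        assert frap.cytoplasmic_concentration(5.0, 1.0, 1.0, 3.0) == pytest.approx(0.5)

    def test_mass_balance(self, rng):
        v_cell = rng.uniform(2, 10, 50)
        v_nuc = v_cell * rng.uniform(0.1, 0.5, 50)
        c_cell = rng.uniform(0.5, 5, 50)
        c_nuc = c_cell * rng.uniform(0.5, 1.5, 50)
        c_cyt = frap.cytoplasmic_concentration(v_cell, c_cell, v_nuc, c_nuc)
        np.testing.assert_allclose(
            c_cyt * (v_cell - v_nuc) + c_nuc * v_nuc, c_cell * v_cell, rtol=1e-12
        )

    def test_inconsistent_measurements_flagged(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            frap.cytoplasmic_concentration(2.0, 1.0, 1.0, 3.0)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            frap.cytoplasmic_concentration(1.0, 1.0, 2.0, 1.0)


class TestCompartmentStats:
    def test_constant_cells(self):
        cells = pd.DataFrame(
            {"V_cell": [5.27] * 5, "V_nuc": [1.0] * 5,
             "c_cell": [1.0] * 5, "c_nuc": [1.1] * 5}
        )
        stats = frap.compartment_stats(cells, n_boot=50)
        assert stats.f_v_mean == pytest.approx(4.27)
        assert stats.f_v_se == 0.0
        assert np.isnan(stats.cor_fv_v)

    def test_independent_fractions_uncorrelated(self, rng):
        n = 500
        v_cell = rng.lognormal(7, 0.3, n)
        f_v = rng.lognormal(np.log(4.27), 0.1, n)  # independent of V
        v_nuc = v_cell / (1 + f_v)
        c_cell = rng.lognormal(0, 0.5, n)
        c_nuc = c_cell * rng.uniform(0.9, 1.4, n)
        cells = pd.DataFrame(
            {"V_cell": v_cell, "V_nuc": v_nuc, "c_cell": c_cell, "c_nuc": c_nuc}
        )
        stats = frap.compartment_stats(cells, n_boot=300, seed=1)
        assert abs(stats.cor_fv_v) < 0.1
        assert abs(stats.cor_fv_v) < 2 * stats.cor_fv_v_se + 0.1

    def test_too_few_cells_rejected(self):
        cells = pd.DataFrame(
            {"V_cell": [5.0], "V_nuc": [1.0], "c_cell": [1.0], "c_nuc": [1.0]}
        )
        with pytest.raises(ValueError):
            frap.compartment_stats(cells)
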