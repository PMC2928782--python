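"""Calibration-scale transforms, QQ regression and the cut-off scan.

Expected values are closed forms or brute-force computations on tiny
inputs; parameter-recovery checks simulate from a known affine link.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cytolink import calibration as cal
from cytolink import gating, synth


class TestScaleTransforms:
    def test_log_intensity_values_and_order(self):
        np.testing.assert_allclose(
            cal.log_intensity([1.0, np.e, np.e**2, np.e**4]), [0, 1, 2, 4]
        )

    def test_log_intensity_names_offender(self):
        with pytest.raises(ValueError, match=r"record\(s\) \[1\]"):
            cal.log_intensity([1.0, -2.0, 3.0])

    def test_sphere_cross_section_values(self):
        assert cal.sphere_cross_section([1.0])[0] == pytest.approx(
            (36 * np.pi) ** (1 / 3), rel=1e-12
        )
        # homogeneity of degree 2/3
        assert cal.sphere_cross_section([8.0])[0] == pytest.approx(
            4 * cal.sphere_cross_section([1.0])[0], rel=1e-12
        )

    def test_sphere_round_trip(self, rng):
        v = rng.uniform(10, 5000, 100)
        np.testing.assert_allclose(
            cal.sphere_volume(cal.sphere_cross_section(v)), v, rtol=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cal.sphere_cross_section([0.0])


class TestSampleQuantiles:
    def test_full_size_returns_sorted_sample(self, rng):
        v = rng.normal(size=37)
        np.testing.assert_array_equal(cal.sample_quantiles(v, 37), np.sort(v))

    def test_uniform_grid_positions(self):
        v = np.arange(10000, dtype=float)
        q = cal.sample_quantiles(v, 4)
        # brute-force order statistic at p=(i-0.5)/4: index ceil(10000 p)-1
        np.testing.assert_allclose(q, [1249, 3749, 6249, 8749], atol=1.0)

    def test_degenerate_distribution(self):
        np.testing.assert_array_equal(
            cal.sample_quantiles(np.full(5, 3.2), 3), [3.2, 3.2, 3.2]
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cal.sample_quantiles([], 4)


class TestFitQQ:
    def test_identity_calibration(self, rng):
        q = np.sort(rng.normal(size=100))
        m = cal.fit_qq(q, q, n_boot=0)
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)
        assert m.chi2 == pytest.approx(0.0, abs=1e-20)

    def test_exact_affine(self, rng):
        q = np.sort(rng.normal(size=50))
        m = cal.fit_qq(q, 2 * q + 3, n_boot=0)
        assert m.slope == pytest.approx(2.0, rel=1e-12)
        assert m.intercept == pytest.approx(3.0, rel=1e-12)

    def test_location_scale_equivariance(self, rng):
        x = np.sort(rng.normal(size=80))
        y = np.sort(rng.normal(1.0, 2.0, size=80))
        m0 = cal.fit_qq(x, y, n_boot=0)
        m1 = cal.fit_qq(3 * x - 1, y, n_boot=0)  # shift/scale the abscissa
        assert m1.slope == pytest.approx(m0.slope / 3, rel=1e-10)
        assert m1.intercept == pytest.approx(m0.intercept + m0.slope / 3, rel=1e-8)

    def test_parameter_recovery_within_3_se(self):
        # known affine link between comparable scales, many replicates
        true_s, true_i = 0.5, -1.2
        hits_s = hits_i = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(2000 + s)
            xc = rng.normal(0.4, 0.6, 200)
            xt = true_s * rng.normal(0.4, 0.6, 20000) + true_i
            m = cal.fit_qq(
                cal.sample_quantiles(xc, 200), cal.sample_quantiles(xt, 200), seed=s
            )
            hits_s += abs(m.slope - true_s) <= 3 * m.se_slope
            hits_i += abs(m.intercept - true_i) <= 3 * m.se_intercept
        assert hits_s >= 0.95 * n_rep
        assert hits_i >= 0.95 * n_rep

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_qq([1, 2, 3], [1, 2, 3], n_boot=0)


class TestTranslate:
    def test_identity_and_arithmetic(self):
        m = cal.CalibrationMap(2.0, 3.0, 0, 0, 0, 0.66, 10)
        assert cal.translate([5.0], m, "c_to_t")[0] == pytest.approx(13.0)
        assert cal.translate([13.0], m, "t_to_c")[0] == pytest.approx(5.0)

    @given(hst.floats(-50, 50))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_exact(self, x):
        m = cal.CalibrationMap(0.37, -2.1, 0, 0, 0, 0.66, 10)
        back = cal.translate(cal.translate([x], m, "c_to_t"), m, "t_to_c")[0]
        assert back == pytest.approx(x, abs=1e-10)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            cal.CalibrationMap(0.0, 1.0, 0, 0, 0, 0.66, 10)


class TestPenalty:
    def test_closed_form_expectation_is_one(self):
        # E[(n+1) p^n] over U(0,1) = 1: exact integral
        for n in (1, 2, 3):
            p = np.linspace(0, 1, 200001)
            assert np.trapezoid(cal.penalty_factor(p, n), p) == pytest.approx(
                1.0, rel=1e-6
            )

    def test_monte_carlo_expectation(self, rng):
        p = rng.uniform(size=10**6)
        vals = cal.penalty_factor(p, 2)
        se = vals.std(ddof=1) / 1000
        assert abs(vals.mean() - 1.0) < 3 * se


class TestScanCutoff:
    def test_penalty_term_vanishes_at_p_zero(self, rng):
        # grid below all data: nothing dropped, objective reduces to chi2/2
        xm = rng.normal(size=200)
        xf = rng.normal(size=2000) + 10
        grid = np.linspace(xf.min(), xf.min() + 1e-9, 3)
        scan = cal.scan_cutoff(xf, xm, grid=grid)
        keepmask = np.isfinite(scan.chi2)
        assert np.all(scan.p[keepmask] <= 1e-3)
        np.testing.assert_allclose(
            scan.objective[keepmask],
            0.5 * scan.chi2[keepmask] * (1 + cal.penalty_factor(scan.p[keepmask], 2)),
        )

    def test_dim_subpopulation_threshold_recovered(self):
        # distinct non-expressing component below the detection limit
        truth0 = synth.PopulationTruth()
        thr = truth0.conc_dist.mu - 2.326 * truth0.conc_dist.sigma
        truth = synth.PopulationTruth(
            n_cells=50000, n_micro=20000, dim_threshold=thr, dim_fraction=0.2, seed=3
        )
        micro, flow = synth.generate_paired_population(truth)
        g = gating.gate_events(flow, gating.choose_cuts(flow, gating.fit_scatter_axis(flow)))
        scan = cal.scan_cutoff(np.asarray(g["F2"]), cal.log_intensity(micro["intensity"]))
        z_true = truth.intensity_link.forward(thr)
        step = scan.grid[1] - scan.grid[0]
        assert abs(scan.z_star - z_true) <= step

    def test_no_dim_subpopulation_keeps_full_data(self):
        truth = synth.PopulationTruth(n_cells=20000, n_micro=5000, seed=4)
        micro, flow = synth.generate_paired_population(truth)
        g = gating.gate_events(flow, gating.choose_cuts(flow, gating.fit_scatter_axis(flow)))
        scan = cal.scan_cutoff(np.asarray(g["F2"]), cal.log_intensity(micro["intensity"]))
        dropped = scan.p[int(np.argmin(scan.objective))]
        assert dropped <= 0.02

    def test_sparse_grid_points_excluded_with_warning(self, rng):
        xm = rng.normal(size=50)
        xf = rng.normal(size=60)
        grid = np.quantile(xf, [0.0, 0.5, 0.95])  # last Z leaves <10 values
        with pytest.warns(UserWarning, match="excluded"):
            scan = cal.scan_cutoff(xf, xm, grid=grid, min_retained=10)
        assert not np.isfinite(scan.objective[-1])
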