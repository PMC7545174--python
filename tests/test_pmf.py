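"""Jarzynski estimator, force profiles and scalar reporting."""

import math

import numpy as np
import pytest

import fibmech as fm
from fibmech.constants import PN_PER_KCAL_PER_MOL_ANG, kt
from fibmech.errors import RangeError, ValidationError
from fibmech.pmf import (
    convergence_study,
    fit_delta_g_histogram,
    relative_change,
    report_relative_change,
)
from fibmech.profiles import PMFProfile, WorkEnsemble

THERMAL = kt(300.0)


def make_ensemble(works, grid=None, temperature=300.0, strain_reference=60.0):
    works = np.atleast_2d(np.asarray(works, dtype=float))
    if grid is None:
        grid = np.arange(works.shape[1], dtype=float)
    return WorkEnsemble(
        extension=grid, works=works, temperature=temperature,
        strain_reference=strain_reference,
    )


class TestJarzynskiEstimator:
    def test_identical_replicates_collapse_to_their_profile(self):
        profile = np.array([0.0, 1.3, 5.2, 9.9])
        ensemble = make_ensemble(np.tile(profile, (6, 1)))
        pmf = fm.jarzynski_pmf(ensemble)
        assert np.allclose(pmf.delta_g, profile, atol=1e-12)

    def test_two_replicates_zero_and_two_kt_endpoint(self):
        # direct evaluation of the exponential average: -ln((1 + e^-2)/2)
        expected = -THERMAL * math.log((1.0 + math.exp(-2.0)) / 2.0)
        works = np.array([[0.0, 0.0], [0.0, 2.0 * THERMAL]])
        pmf = fm.jarzynski_pmf(make_ensemble(works))
        assert pmf.delta_g[-1] == pytest.approx(expected, abs=1e-12)
        assert pmf.delta_g[-1] / THERMAL == pytest.approx(0.56622, abs=1e-4)

    def test_permutation_invariance(self, rng):
        works = np.hstack([np.zeros((5, 1)), rng.uniform(0, 10, size=(5, 7))])
        ensemble = make_ensemble(works)
        shuffled = make_ensemble(works[rng.permutation(5)])
        assert np.allclose(
            fm.jarzynski_pmf(ensemble).delta_g, fm.jarzynski_pmf(shuffled).delta_g
        )

    def test_huge_work_replicate_shifts_only_by_sample_size_factor(self):
        # a replicate with effectively infinite work contributes nothing to
        # the exponential sum; the estimate moves by exactly kT ln((n+1)/n)
        works = np.array([[0.0, 2.0], [0.0, 3.0], [0.0, 4.0]])
        base = fm.jarzynski_pmf(make_ensemble(works)).delta_g[-1]
        extended = np.vstack([works, [0.0, 1e6]])
        with_inf = fm.jarzynski_pmf(make_ensemble(extended)).delta_g[-1]
        assert np.isfinite(with_inf)
        assert with_inf - base == pytest.approx(THERMAL * math.log(4 / 3), abs=1e-9)

    def test_estimate_never_exceeds_mean_work(self, rng):
        works = np.hstack([np.zeros((20, 1)), rng.normal(5, 2, size=(20, 9))])
        ensemble = make_ensemble(works)
        pmf = fm.jarzynski_pmf(ensemble)
        assert np.all(pmf.delta_g <= ensemble.mean_work() + 1e-9)

    def test_grid_and_start_validation(self):
        with pytest.raises(ValidationError):
            make_ensemble(np.array([[1.0, 2.0]]))  # work must start at 0
        with pytest.raises(ValidationError):
            WorkEnsemble(
                extension=np.array([0.0, 1.0, 0.5]),
                works=np.zeros((1, 3)),
                temperature=300.0,
            )

    def test_benchmark_recovers_analytic_harmonic_pmf(self, benchmark_run):
        pmf = fm.jarzynski_pmf(benchmark_run["ensemble"])
        residual = pmf.delta_g - benchmark_run["reference"].delta_g
        rmse = float(np.sqrt(np.mean(residual**2)))
        assert rmse < 0.5 * THERMAL


class TestDeltaGAtStrain:
    def make_linear_pmf(self):
        grid = np.linspace(0.0, 30.0, 31)
        return PMFProfile(
            extension=grid, delta_g=grid * (51.0 / 30.0), strain_reference=60.0
        )

    def test_zero_strain_is_zero(self):
        assert fm.delta_g_at_strain(self.make_linear_pmf(), 0.0) == 0.0

    def test_linear_profile_endpoint_is_delta_g50(self):
        assert fm.delta_g_at_strain(self.make_linear_pmf(), 50.0) == pytest.approx(51.0)

    def test_interpolation_at_quarter_strain(self):
        assert fm.delta_g_at_strain(self.make_linear_pmf(), 25.0) == pytest.approx(25.5)

    def test_out_of_range_raises(self):
        with pytest.raises(RangeError):
            fm.delta_g_at_strain(self.make_linear_pmf(), 60.0)


class TestForceProfile:
    def test_quadratic_pmf_interior_force(self):
        grid = np.linspace(0.0, 4.0, 401)
        pmf = PMFProfile(extension=grid, delta_g=0.5 * grid**2)
        force = fm.force_profile(pmf, window=0.0)
        idx = np.argmin(np.abs(grid - 2.0))
        assert force.force[idx] == pytest.approx(2.0 * PN_PER_KCAL_PER_MOL_ANG, rel=1e-4)

    def test_constant_pmf_gives_zero_force(self):
        grid = np.linspace(0.0, 4.0, 41)
        pmf = PMFProfile(extension=grid, delta_g=np.zeros_like(grid))
        assert np.allclose(fm.force_profile(pmf, window=0.0).force, 0.0)

    def test_force_integrates_back_to_the_pmf(self, rng):
        grid = np.linspace(0.0, 5.0, 2001)
        coeffs = rng.normal(size=4)
        dg = sum(c * grid ** (k + 1) for k, c in enumerate(coeffs))
        pmf = PMFProfile(extension=grid, delta_g=dg)
        force = fm.force_profile(pmf, window=0.0)
        recovered = np.concatenate(
            [[0.0], np.cumsum(
                0.5 * (force.force[1:] + force.force[:-1]) * np.diff(grid)
            )]
        ) / PN_PER_KCAL_PER_MOL_ANG
        scale = np.max(np.abs(dg))
        assert np.max(np.abs(recovered - dg)) / scale < 1e-6

    def test_metadata_window_matches_ten_ns_rule(self):
        grid = np.linspace(0.0, 30.0, 301)
        pmf = PMFProfile(
            extension=grid, delta_g=grid, metadata={"pull_speed": 0.1}
        )
        force = fm.force_profile(pmf)  # 0.1 Å/ns × 10 ns = 1 Å window
        assert force.smoothing_window == pytest.approx(1.0)

    def test_window_below_grid_spacing_rejected(self):
        grid = np.linspace(0.0, 10.0, 11)
        pmf = PMFProfile(extension=grid, delta_g=grid)
        with pytest.raises(ValidationError):
            fm.force_profile(pmf, window=0.5)


class TestForceSummary:
    def test_linear_ramp_mean_is_midpoint(self):
        grid = np.linspace(0.0, 30.0, 3001)
        force = fm.profiles.ForceProfile(
            extension=grid, force=np.linspace(0, 100, grid.size), strain_reference=60.0
        )
        summary = fm.summarize_forces(force, [(0.0, 50.0)])
        assert summary.window_means["mean_pN"][0] == pytest.approx(50.0, abs=0.1)

    def test_constant_force_window(self):
        grid = np.linspace(0.0, 30.0, 301)
        force = fm.profiles.ForceProfile(
            extension=grid, force=np.full(grid.size, 74.0), strain_reference=60.0
        )
        summary = fm.summarize_forces(force, [(0.0, 20.0)])
        assert summary.window_means["mean_pN"][0] == pytest.approx(74.0)
        assert summary.window_means["sd_pN"][0] == pytest.approx(0.0)

    def test_sawtooth_peak_location(self):
        grid = np.linspace(0.0, 30.0, 301)
        force_vals = np.abs((grid % 10.0) - 5.0)
        force_vals[150] = 20.0  # constructed maximum at 15 Å = 25% strain
        force = fm.profiles.ForceProfile(
            extension=grid, force=force_vals, strain_reference=60.0
        )
        summary = fm.summarize_forces(force)
        assert summary.peak_force == pytest.approx(20.0)
        assert summary.peak_strain == pytest.approx(25.0)

    def test_empty_window_rejected(self):
        grid = np.linspace(0.0, 30.0, 31)
        force = fm.profiles.ForceProfile(
            extension=grid, force=np.zeros(31), strain_reference=60.0
        )
        with pytest.raises(ValidationError):
            fm.summarize_forces(force, [(20.0, 20.0)])


class TestRelativeChange:
    def test_printed_rounding_convention(self):
        assert report_relative_change(51.0, 36.0) == 29
        assert report_relative_change(227.0, 169.0) == 26

    def test_identity_is_zero(self):
        assert report_relative_change(13.7, 13.7) == 0

    def test_sign_convention_increase_is_negative(self):
        assert relative_change(50.0, 75.0) == pytest.approx(-50.0)
        assert report_relative_change(50.0, 75.0) == -50

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            relative_change(0.0, 1.0)


class TestDeltaGHistogram:
    def test_hand_arithmetic_moments(self):
        works = np.array([[0.0, 10.0], [0.0, 12.0], [0.0, 14.0]])
        grid = np.array([0.0, 30.0])
        hist = fit_delta_g_histogram(make_ensemble(works, grid=grid), strain=50.0)
        assert hist.location == pytest.approx(12.0)
        assert hist.scale == pytest.approx(2.0)

    def test_degenerate_spread_is_zero(self):
        works = np.tile([0.0, 7.0], (4, 1))
        grid = np.array([0.0, 30.0])
        hist = fit_delta_g_histogram(make_ensemble(works, grid=grid), strain=50.0)
        assert hist.scale == 0.0

    def test_single_replicate_rejected(self):
        works = np.array([[0.0, 7.0]])
        with pytest.raises(ValidationError):
            fit_delta_g_histogram(make_ensemble(works, grid=np.array([0.0, 30.0])))

    def test_normal_draw_moments_within_sampling_error(self, rng):
        n = 1000
        values = rng.normal(50.0, 5.0, size=n)
        works = np.hstack([np.zeros((n, 1)), values[:, None]])
        hist = fit_delta_g_histogram(
            make_ensemble(works, grid=np.array([0.0, 30.0])), strain=50.0
        )
        se_mean = 5.0 / math.sqrt(n)
        se_sd = 5.0 / math.sqrt(2 * n)
        assert abs(hist.location - 50.0) < 3 * se_mean
        assert abs(hist.scale - 5.0) < 3 * se_sd


class TestConvergenceStudy:
    def test_single_trajectory_estimate_is_its_endpoint_work(self):
        potential, steer, cfg = fm.synthetic.harmonic_benchmark(
            seed=5, n_replicates=1, pull_speed=1.0
        )
        report = convergence_study(potential, steer, [1.0], [1], cfg)
        _, single = fm.simulate_steered_trajectory(potential, steer, cfg)
        assert report.shape[0] == 1
        assert report["delta_g_end"][0] == pytest.approx(single.work[-1])

    def test_cross_product_table_shape(self):
        potential, steer, cfg = fm.synthetic.harmonic_benchmark(
            seed=5, n_replicates=4, pull_speed=1.0
        )
        report = convergence_study(potential, steer, [2.0, 1.0], [2, 4], cfg)
        assert report.shape[0] == 4
        assert set(report.columns) == {"pull_speed", "n_samples", "delta_g_end", "bias"}

    def test_empty_inputs_rejected(self):
        potential, steer, cfg = fm.synthetic.harmonic_benchmark()
        with pytest.raises(ValidationError):
            convergence_study(potential, steer, [], [10], cfg)
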