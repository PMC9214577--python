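"""Spectral error, calibration, parameter space, multistart fitting and
multiple-solution selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from headfit.chromophores import default_fit_wavelengths
from headfit.inverse import (FitResult, FitTarget, build_initial_pool,
                             calibrate_spectra, fit_multistart,
                             select_solutions, spectral_error)


class TestSpectralError:
    def test_identical_spectra_zero_error(self):
        R = np.random.default_rng(0).uniform(1e-6, 1e-2, (22, 6))
        assert spectral_error(R, R) == 0.0

    def test_constant_ten_percent_ratio(self):
        R = np.random.default_rng(1).uniform(1e-6, 1e-2, (22, 6))
        assert spectral_error(1.1 * R, R) == pytest.approx(0.1, abs=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_common_positive_rescaling(self, scale):
        rng = np.random.default_rng(2)
        Rm = rng.uniform(1e-6, 1e-2, (10, 4))
        Rs = Rm * rng.uniform(0.8, 1.2, (10, 4))
        spectrum = scale * rng.uniform(0.5, 2.0, (10, 1))
        assert spectral_error(Rs * spectrum, Rm * spectrum) \
            == pytest.approx(spectral_error(Rs, Rm), rel=1e-9)

    def test_detector_subset(self):
        Rm = np.ones((5, 3))
        Rs = np.ones((5, 3))
        Rs[:, 2] = 2.0
        assert spectral_error(Rs, Rm, detectors=[0, 1]) == 0.0
        assert spectral_error(Rs, Rm, detectors=[2]) == pytest.approx(1.0)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            spectral_error(np.ones((2, 2)), np.zeros((2, 2)))


class TestCalibration:
    def _stacks(self, slope=1.0, offset=0.0, n_phantom=6):
        rng = np.random.default_rng(3)
        sim = rng.uniform(1e-5, 1e-2, (n_phantom, 8, 3))
        meas = (sim - offset) / slope
        return meas, sim

    def test_identity_pairs_pass_through(self):
        meas, sim = self._stacks()
        lam = np.linspace(700, 880, 8)
        target = calibrate_spectra(meas, sim, meas[0], lam, (0, 1))
        assert np.allclose(target.reflectance, sim[0])

    def test_doubling_pairs_double_target(self):
        meas, sim = self._stacks(slope=2.0)
        lam = np.linspace(700, 880, 8)
        target = calibrate_spectra(meas, sim, meas[0], lam, (0, 1))
        assert np.allclose(target.reflectance, 2.0 * meas[0])

    def test_affine_distortion_recovered_through_noise(self):
        rng = np.random.default_rng(4)
        sim = rng.uniform(1e-4, 1e-2, (6, 10, 2))
        meas = (sim - 2e-4) / 1.7 * (1 + 0.01 * rng.standard_normal(
            sim.shape))
        raw = np.stack([(sim[0] - 2e-4) / 1.7] * 3)  # repeated measurements
        lam = np.linspace(700, 880, 10)
        target = calibrate_spectra(meas, sim, raw, lam, (0,))
        assert np.allclose(target.reflectance, sim[0], rtol=0.05)

    def test_degenerate_phantoms_rejected(self):
        sim = np.ones((3, 5, 2)) * np.array([1e-3, 2e-3])
        meas = np.ones_like(sim)  # identical intensities per detector
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_spectra(meas, sim, meas[0],
                              np.linspace(700, 880, 5), (0,))

    def test_single_phantom_rejected(self):
        meas, sim = self._stacks(n_phantom=1)
        with pytest.raises(ValueError):
            calibrate_spectra(meas, sim, meas[0],
                              np.linspace(700, 880, 8), (0,))


class TestSpectralCalibration:
    def test_wavelength_dependent_response_recovered(self):
        from headfit.inverse import calibrate_spectra_spectral
        rng = np.random.default_rng(9)
        cal_lam = np.linspace(700, 880, 8)
        lam = np.linspace(700, 880, 22)
        sim = rng.uniform(1e-4, 1e-2, (5, 8, 3))
        # spectral instrument response: per-detector gain sloping in lam
        gain_cal = 1.5 + 0.003 * (cal_lam[None, :, None] - 700)
        meas = sim / gain_cal
        target_sim = rng.uniform(1e-4, 1e-2, (22, 3))
        gain_t = 1.5 + 0.003 * (lam[:, None] - 700)
        raw = target_sim / gain_t
        ft = calibrate_spectra_spectral(meas, sim, cal_lam, raw, lam,
                                        (0, 1))
        assert np.allclose(ft.reflectance, target_sim, rtol=1e-6)

    def test_identity_response_passes_through(self):
        from headfit.inverse import calibrate_spectra_spectral
        rng = np.random.default_rng(10)
        cal_lam = np.linspace(700, 880, 4)
        sim = rng.uniform(1e-4, 1e-2, (4, 4, 2))
        ft = calibrate_spectra_spectral(sim, sim, cal_lam, sim[0],
                                        cal_lam, (0,))
        assert np.allclose(ft.reflectance, sim[0])


class TestFitTarget:
    def test_overlapping_detector_sets_rejected(self):
        with pytest.raises(ValueError):
            FitTarget(wavelengths=np.array([700.0]),
                      reflectance=np.ones((1, 6)),
                      fit_detectors=(0, 1), tiebreak_detectors=(1, 2))


class TestParamSpace:
    def test_vector_round_trip(self, phantom_bundle):
        space = phantom_bundle["space"]
        rng = np.random.default_rng(5)
        vec = space.sample_valid(1, rng, default_fit_wavelengths())[0]
        params = space.to_params(vec)
        assert np.allclose(space.from_params(params), vec, rtol=1e-10)

    def test_batch_ops_match_reference_path(self, phantom_bundle, lib,
                                            ranges):
        from headfit.chromophores import params_to_op_spectra
        space = phantom_bundle["space"]
        lam = default_fit_wavelengths()
        rng = np.random.default_rng(6)
        vec = space.sample_valid(1, rng, lam)[0]
        fast = space.op_matrix_batch(vec[None], lam)[0]
        slow = params_to_op_spectra(space.to_params(vec), lib, ranges,
                                    lam).op_matrix()
        assert np.allclose(fast, slow, rtol=1e-10)

    def test_sampled_vectors_satisfy_constraints(self, phantom_bundle):
        space = phantom_bundle["space"]
        lam = default_fit_wavelengths()
        rng = np.random.default_rng(7)
        for vec in space.sample_valid(25, rng, lam):
            assert np.all(space.constraint_margins(vec, lam) >= -1e-12)


class TestInitialPool:
    def test_same_seed_identical_pool(self, phantom_bundle):
        sur = phantom_bundle["surrogate"]
        space = phantom_bundle["space"]
        a = build_initial_pool(sur, space, n=40, rng=9)
        b = build_initial_pool(sur, space, n=40, rng=9)
        assert np.array_equal(a.vectors, b.vectors)
        assert np.array_equal(a.spectra, b.spectra)

    def test_self_retrieval_has_zero_error(self, phantom_bundle):
        pool = phantom_bundle["pool"]
        k = 3
        target = pool.spectra[k]
        errs = np.sqrt(np.mean(
            (pool.spectra / target[None] - 1.0) ** 2, axis=(1, 2)))
        assert errs.argmin() == k
        assert errs[k] == 0.0

    def test_too_small_pool_rejected(self, phantom_bundle):
        with pytest.raises(ValueError):
            build_initial_pool(phantom_bundle["surrogate"],
                               phantom_bundle["space"], n=5)


class TestMultistartFitting:
    @pytest.fixture(scope="class")
    def self_target_fit(self, phantom_bundle):
        """Fit three targets generated by the surrogate itself
        (noiseless); returns the last target's details plus the best
        spectral error per target."""
        sur = phantom_bundle["surrogate"]
        space = phantom_bundle["space"]
        pool = phantom_bundle["pool"]
        lam = pool.wavelengths
        best_errors = []
        for seed in (11, 12, 13):
            rng = np.random.default_rng(seed)
            vec = space.sample_valid(1, rng, lam)[0]
            ops = space.op_matrix_batch(vec[None], lam)[0]
            R = sur.predict_reflectance(ops, warn_out_of_range=False)
            target = FitTarget(wavelengths=lam, reflectance=R,
                               fit_detectors=(0, 1, 2, 3, 4),
                               tiebreak_detectors=(5,))
            results = fit_multistart(target, sur, pool, space=space,
                                     n_starts=8, max_iter=200)
            best_errors.append(results[0].error_fit)
        return target, results, vec, best_errors

    def test_noiseless_self_recovery_below_two_percent(self,
                                                       self_target_fit):
        # typical-case property: a self-consistent noiseless target is
        # recovered essentially exactly; rare targets near constraint
        # corners can stall a few percent higher
        *_, best_errors = self_target_fit
        assert np.median(best_errors) < 0.02, best_errors

    def test_results_sorted_by_error(self, self_target_fit):
        _, results, _, _ = self_target_fit
        errs = [r.error_fit for r in results]
        assert errs == sorted(errs)

    def test_objective_identity_recomputed_from_scratch(
            self, self_target_fit, phantom_bundle):
        target, results, _, _ = self_target_fit
        sur = phantom_bundle["surrogate"]
        best = results[0]
        R = sur.predict_reflectance(best.op_spectra,
                                    warn_out_of_range=False)
        recomputed = spectral_error(R, target.reflectance,
                                    target.fit_detectors)
        assert recomputed == pytest.approx(best.error_fit, rel=1e-12)

    def test_constraints_satisfied_at_every_wavelength(self,
                                                       self_target_fit,
                                                       phantom_bundle):
        target, results, _, _ = self_target_fit
        space = phantom_bundle["space"]
        for r in results:
            assert np.all(space.constraint_margins(
                r.vector, target.wavelengths) >= -1e-6)

    def test_pool_smaller_than_starts_rejected(self, phantom_bundle):
        sur = phantom_bundle["surrogate"]
        space = phantom_bundle["space"]
        pool = build_initial_pool(sur, space, n=20, rng=3)
        lam = pool.wavelengths
        target = FitTarget(wavelengths=lam,
                           reflectance=np.full((len(lam), 6), 1e-4),
                           fit_detectors=(0, 1))
        with pytest.raises(ValueError):
            fit_multistart(target, sur, pool, space=space, n_starts=50)


class TestDetectorCombinationScan:
    def test_largest_combination_below_threshold_chosen(self,
                                                        phantom_bundle):
        from headfit.inverse import scan_detector_combinations
        sur = phantom_bundle["surrogate"]
        space = phantom_bundle["space"]
        pool = phantom_bundle["pool"]
        lam = pool.wavelengths
        rng = np.random.default_rng(21)
        vec = space.sample_valid(1, rng, lam)[0]
        ops = space.op_matrix_batch(vec[None], lam)[0]
        R = sur.predict_reflectance(ops, warn_out_of_range=False)
        out = scan_detector_combinations(
            R, lam, [(0, 1, 2), (0, 1, 2, 3, 4)], sur, pool, space,
            n_starts=3, max_iter=60)
        assert out["chosen"] == (0, 1, 2, 3, 4)
        assert set(out["outcomes"]) == {(0, 1, 2), (0, 1, 2, 3, 4)}
        for o in out["outcomes"].values():
            assert o["error"] < 0.15  # noiseless self-consistent target


def _fr(err_fit, err_tie):
    return FitResult(params=None, vector=np.zeros(13),
                     op_spectra=np.zeros((1, 8)), error_fit=err_fit,
                     error_tiebreak=err_tie, start_index=0,
                     n_iterations=10, converged=True)


class TestSelectSolutions:
    def test_single_dominant_solution(self):
        results = [_fr(0.05, 0.06), _fr(0.09, 0.05), _fr(0.2, 0.3)]
        sol = select_solutions(results, threshold=0.02)
        assert not sol.multiple
        assert len(sol.solutions) == 1
        assert sol.solutions[0].error_fit == 0.05

    def test_two_stage_filtering(self):
        # stage 1 keeps the three within 2% of 0.05; stage 2 keeps the
        # two within 2% of the best tie-breaker error among those
        results = [_fr(0.05, 0.10), _fr(0.06, 0.11), _fr(0.065, 0.20),
                   _fr(0.10, 0.01)]
        sol = select_solutions(results, threshold=0.02)
        assert sol.stage1_count == 3
        assert len(sol.solutions) == 2
        assert sol.multiple

    def test_forced_tie_reports_multiplicity(self):
        results = [_fr(0.050, 0.070), _fr(0.055, 0.075)] \
            + [_fr(0.2, 0.2)] * 3
        sol = select_solutions(results, threshold=0.02)
        assert sol.multiple
        assert len(sol.solutions) == 2

    def test_zero_threshold_keeps_exact_minima_only(self):
        results = [_fr(0.05, 0.08), _fr(0.05 + 1e-9, 0.08), _fr(0.3, 0.3)]
        sol = select_solutions(results, threshold=0.0)
        assert len(sol.solutions) == 1

    def test_no_tiebreak_detectors_skips_stage_two(self):
        results = [_fr(0.05, np.nan), _fr(0.06, np.nan)]
        sol = select_solutions(results, threshold=0.02)
        assert len(sol.solutions) == 2

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_solutions([])
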