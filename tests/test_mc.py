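"""Photon transport engine: determinism, acceptance, energy bookkeeping,
pathlength physics and the white-MC / absorbing-MC equivalence."""

import numpy as np
import pytest

from conftest import TYPICAL_MUA, TYPICAL_MUSP
from headfit.head_model import VoxelHeadModel, place_probe, ring_probe
from headfit.mc import (mean_partial_pathlength, mua_dict_to_array,
                        reflectance_from_records, reflectance_with_error,
                        run_absorbing_mc, run_white_mc)


class TestDeterminismAndAcceptance:
    def test_same_seed_bit_identical_records(self, head_slab, head_rings):
        a = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 30_000,
                         acceptance_na=1.0, rng=7, path_cap_cm=80)
        b = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 30_000,
                         acceptance_na=1.0, rng=7, path_cap_cm=80)
        assert np.array_equal(a.pathlengths, b.pathlengths)
        assert np.array_equal(a.det_id, b.det_id)
        assert np.array_equal(a.exit_angle, b.exit_angle)

    def test_different_seeds_agree_within_binomial_error(self, head_slab,
                                                         head_rings):
        a = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 60_000,
                         acceptance_na=1.0, rng=1, path_cap_cm=80)
        b = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 60_000,
                         acceptance_na=1.0, rng=2, path_cap_cm=80)
        for d in range(3):  # short separations have the statistics
            na, nb = a.n_detected[d], b.n_detected[d]
            sigma = np.sqrt(na + nb)
            assert abs(na - nb) < 5 * sigma

    def test_low_na_exit_angles_bounded(self, head_slab):
        probe = place_probe(head_slab, detector_radius_cm=0.3,
                            anchor_cm=(2.0, 5.0))
        res = run_white_mc(head_slab, probe, TYPICAL_MUSP, 40_000,
                           acceptance_na=0.12, rng=3, path_cap_cm=80)
        assert res.n_total == 40_000
        if len(res.exit_angle):
            assert res.exit_angle.max() <= np.arcsin(0.12 / 1.457) + 1e-12

    def test_acceptance_filter_matches_direct_low_na(self, head_slab,
                                                     head_rings, head_wmc):
        direct = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 150_000,
                              acceptance_na=0.12, rng=42, path_cap_cm=150)
        view = head_wmc.filter_acceptance(0.12)
        # same seed, same trajectories: the filtered wide-open run must
        # reproduce the direct low-NA run exactly
        assert np.array_equal(np.sort(view.pathlengths[:, 0]),
                              np.sort(direct.pathlengths[:, 0]))


class TestEnergyBookkeeping:
    def test_counts_partition_photon_budget(self, head_wmc):
        c = head_wmc.counts
        assert (c["detected"] + c["escaped"] + c["capped"] + c["specular"]
                == head_wmc.n_total)
        assert head_wmc.n_detected.sum() == c["detected"]

    def test_near_unity_escape_with_zero_absorption(self, homogeneous_model):
        # with mu_a = 0 everything that is not specularly reflected leaves
        # the volume apart from the small capped tail
        probe = ring_probe(homogeneous_model, sds_list_cm=(1.0,),
                           acceptance_na=1.0)
        res = run_white_mc(homogeneous_model, probe,
                           {"scalp": 10, "skull": 10, "csf": 10, "gm": 10},
                           40_000, rng=5, path_cap_cm=300)
        c = res.counts
        exited = (c["detected"] + c["escaped"]) / res.n_total
        assert c["capped"] / res.n_total < 0.03
        assert exited > 0.96

    def test_specular_fraction_matches_fresnel_at_normal_incidence(
            self, homogeneous_model):
        # pencil beam: launch NA -> 0, normal incidence 1.457 -> 1.4
        probe = ring_probe(homogeneous_model, sds_list_cm=(1.0,),
                           source_radius_cm=0.0, source_na=0.0,
                           acceptance_na=1.0)
        res = run_white_mc(homogeneous_model, probe,
                           {"scalp": 10, "skull": 10, "csf": 10, "gm": 10},
                           200_000, rng=9, path_cap_cm=10)
        r_expected = ((1.457 - 1.4) / (1.457 + 1.4)) ** 2
        n_exp = res.n_total * r_expected
        assert abs(res.counts["specular"] - n_exp) < 4 * np.sqrt(n_exp)


class TestBeerLambertRescaling:
    def test_zero_absorption_gives_detection_fraction(self, head_wmc):
        R = reflectance_from_records(head_wmc, np.zeros(5))
        assert np.allclose(R, head_wmc.n_detected / head_wmc.n_total)

    def test_single_photon_closed_form(self):
        from headfit.mc import WMCResult
        res = WMCResult(det_id=np.array([0]),
                        pathlengths=np.array([[1.0, 0, 0, 0, 0.]]),
                        exit_angle=np.array([0.0]), n_total=1000,
                        n_detectors=1, musp_combo={}, acceptance_na=1.0,
                        seed=0)
        R = reflectance_from_records(
            res, {"scalp": 0.3, "skull": 0, "csf": 0, "gm": 0, "wm": 0})
        assert R[0] == pytest.approx(np.exp(-0.3) / 1000)

    def test_monotone_nonincreasing_in_each_mua(self, head_wmc):
        base = mua_dict_to_array(TYPICAL_MUA)
        R0 = reflectance_from_records(head_wmc, base)
        for k in range(5):
            up = base.copy()
            up[k] += 0.1
            R1 = reflectance_from_records(head_wmc, up)
            assert np.all(R1 <= R0 + 1e-15)

    def test_log_reflectance_convex_in_single_mua(self, head_wmc):
        # positive mixture of exponentials: d2(log R)/d mua2 >= 0
        base = mua_dict_to_array(TYPICAL_MUA)
        sweep = np.linspace(0.05, 0.5, 9)
        logs = []
        for v in sweep:
            m = base.copy()
            m[0] = v
            logs.append(np.log(np.maximum(
                reflectance_from_records(head_wmc, m)[:3], 1e-300)))
        logs = np.array(logs)
        second = np.diff(logs, 2, axis=0)
        assert np.all(second > -1e-9)

    def test_absorbing_equals_white_rescaled_same_seed(self, head_slab,
                                                       head_rings):
        white = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 30_000,
                             acceptance_na=1.0, rng=21, path_cap_cm=80)
        absorbed = run_absorbing_mc(head_slab, head_rings, TYPICAL_MUA,
                                    TYPICAL_MUSP, 30_000,
                                    acceptance_na=1.0, rng=21,
                                    path_cap_cm=80)
        assert np.allclose(absorbed,
                           reflectance_from_records(white, TYPICAL_MUA))


class TestPartialPathlengths:
    def test_unweighted_mean_at_zero_absorption(self, head_wmc):
        pl = mean_partial_pathlength(head_wmc, np.zeros(5), detector=0)
        sel = head_wmc.det_id == 0
        assert np.allclose(pl, head_wmc.pathlengths[sel].mean(axis=0))

    def test_derivative_identity(self, head_wmc):
        # mean partial pathlength equals -d ln R / d mua_l
        mua = mua_dict_to_array(TYPICAL_MUA)
        det = 1
        pl = mean_partial_pathlength(head_wmc, mua, det)
        h = 1e-5
        for layer in range(4):
            up = mua.copy()
            dn = mua.copy()
            up[layer] += h
            dn[layer] -= h
            ru = reflectance_from_records(head_wmc, up)[det]
            rd = reflectance_from_records(head_wmc, dn)[det]
            fd = -(np.log(ru) - np.log(rd)) / (2 * h)
            assert fd == pytest.approx(pl[layer], rel=0.01, abs=1e-4)

    def test_gm_pathlength_grows_with_sds(self, head_wmc):
        mua = mua_dict_to_array(TYPICAL_MUA)
        gm_near = mean_partial_pathlength(head_wmc, mua, 0)[3]
        gm_far = mean_partial_pathlength(head_wmc, mua, 4)[3]
        assert gm_far > gm_near

    def test_empty_detector_raises(self, head_wmc):
        with pytest.raises(ValueError):
            mean_partial_pathlength(head_wmc, np.zeros(5),
                                    detector=head_wmc.n_detectors + 3)


class TestCSFTransport:
    """A clear (low-scattering) CSF layer pipes light laterally: photons
    cross the thin layer ballistically (shorter dwell per crossing than a
    diffusing photon) but reach distant detectors more efficiently."""

    @pytest.fixture(scope="class")
    def csf_runs(self, head_slab, head_rings):
        low = run_white_mc(head_slab, head_rings,
                           {"scalp": 18, "skull": 16, "csf": 1.0, "gm": 11},
                           120_000, acceptance_na=1.0, rng=31,
                           path_cap_cm=150)
        high = run_white_mc(head_slab, head_rings,
                            {"scalp": 18, "skull": 16, "csf": 10.0,
                             "gm": 11}, 120_000, acceptance_na=1.0, rng=31,
                            path_cap_cm=150)
        return low, high

    def test_diffusive_csf_dwell_exceeds_ballistic(self, csf_runs):
        low, high = csf_runs
        sel_lo = low.det_id == 1
        sel_hi = high.det_id == 1
        assert high.pathlengths[sel_hi, 2].mean() \
            > low.pathlengths[sel_lo, 2].mean()

    def test_clear_csf_enhances_far_detection(self, csf_runs):
        low, high = csf_runs
        far_lo = int((low.det_id >= 3).sum())
        far_hi = int((high.det_id >= 3).sum())
        assert far_lo > far_hi


class TestPersistence:
    def test_hdf5_round_trip(self, head_wmc, tmp_path):
        path = tmp_path / "wmc.h5"
        head_wmc.save(path)
        from headfit.mc import WMCResult
        back = WMCResult.load(path)
        assert np.array_equal(back.pathlengths, head_wmc.pathlengths)
        assert np.array_equal(back.det_id, head_wmc.det_id)
        assert back.n_total == head_wmc.n_total
        assert back.musp_combo == pytest.approx(head_wmc.musp_combo)


class TestErrorEstimate:
    def test_sigma_scales_with_photon_number(self, head_slab, head_rings):
        small = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 20_000,
                             acceptance_na=1.0, rng=55, path_cap_cm=80)
        _, s_small = reflectance_with_error(small, TYPICAL_MUA)
        big = run_white_mc(head_slab, head_rings, TYPICAL_MUSP, 80_000,
                           acceptance_na=1.0, rng=56, path_cap_cm=80)
        _, s_big = reflectance_with_error(big, TYPICAL_MUA)
        # fourfold photons: sigma roughly halves at the short separations
        assert s_big[0] < s_small[0]
        assert s_big[1] < s_small[1]
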