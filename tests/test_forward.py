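"""Lookup table, interpolation, NA conversion and training-set plumbing."""

import numpy as np
import pytest

from headfit.chromophores import OPRanges
from headfit.forward import (LookupTable, MuspGrid, NAConversionModel,
                             apply_na_conversion, build_lookup_table,
                             fit_na_conversion, generate_training_set,
                             interpolate_reflectance, sample_mua_combos,
                             training_row_count, wmc_reflectance)
from headfit.head_model import ring_probe
from headfit.mc import WMCResult, reflectance_with_error, run_white_mc

MUA = {"scalp": 0.2, "skull": 0.12, "csf": 0.025, "gm": 0.18}


class TestMuspGrid:
    def test_full_scale_cardinality(self):
        grid = MuspGrid.full_scale()
        assert grid.shape == (13, 9, 4, 6)
        assert grid.size == 2808
        assert len(grid.combos()) == 2808

    def test_desk_scale_product(self):
        grid = MuspGrid.desk_scale()
        assert grid.size == np.prod(grid.shape)
        assert grid.size == 54

    def test_custom_product(self):
        grid = MuspGrid(scalp=(5, 15, 25), skull=(5, 20, 35),
                        csf=(1.0, 3.7), gm=(5.0, 35.0))
        assert grid.size == 3 * 3 * 2 * 2

    def test_nodes_must_increase(self):
        with pytest.raises(ValueError):
            MuspGrid(scalp=(10, 5), skull=(5, 20), csf=(1, 3.7),
                     gm=(5, 35))

    def test_full_scale_nodes_span_admissible_ranges(self):
        grid = MuspGrid.full_scale()
        r = OPRanges.default()
        for name in ("scalp", "skull", "csf", "gm"):
            nodes = np.asarray(getattr(grid, name))
            lo, hi = r.musp[name]
            assert nodes[0] == lo and nodes[-1] == hi


class TestLookupTable:
    def test_entry_count_matches_grid(self, micro_lut):
        assert len(micro_lut.results) == micro_lut.grid.size

    def test_rebuild_bit_identical(self, micro_lut, homogeneous_model):
        probe = ring_probe(homogeneous_model, sds_list_cm=(0.8, 1.5, 2.12),
                           ring_halfwidth_cm=0.1, acceptance_na=1.0)
        again = build_lookup_table(homogeneous_model, probe,
                                   micro_lut.grid, n_photons=25_000,
                                   acceptance_na=1.0, base_seed=7,
                                   path_cap_cm=80.0)
        for a, b in zip(micro_lut.results, again.results):
            assert np.array_equal(a.pathlengths, b.pathlengths)

    def test_incomplete_table_flagged(self, micro_lut):
        with pytest.raises(ValueError):
            LookupTable(grid=micro_lut.grid,
                        results=micro_lut.results[:-1],
                        acceptance_na=1.0, base_seed=0)

    def test_hdf5_round_trip(self, micro_lut, tmp_path):
        path = tmp_path / "lut.h5"
        micro_lut.save(path)
        back = LookupTable.load(path)
        assert back.grid.shape == micro_lut.grid.shape
        for a, b in zip(back.results, micro_lut.results):
            assert np.array_equal(a.pathlengths, b.pathlengths)
            assert a.musp_combo == pytest.approx(b.musp_combo)


class TestInterpolation:
    def test_grid_node_query_exact(self, micro_lut):
        node = 5
        combo = micro_lut.grid.combo_dict(node)
        direct = wmc_reflectance(micro_lut.results[node], MUA)
        interp = interpolate_reflectance(micro_lut, combo, MUA)
        pos = direct > 0
        assert np.allclose(interp[pos], direct[pos], rtol=1e-9)

    def test_outside_hull_rejected(self, micro_lut):
        with pytest.raises(ValueError):
            interpolate_reflectance(
                micro_lut, {"scalp": 40.0, "skull": 20, "csf": 2, "gm": 20},
                MUA)

    def test_monotone_decreasing_in_mua_at_fixed_query(self, micro_lut):
        # the micro model is uniform gray matter, so sweep the GM (and
        # coupled WM) absorption
        q = {"scalp": 15.0, "skull": 15.0, "csf": 2.0, "gm": 15.0}
        sweep = np.linspace(0.05, 0.5, 6)
        vals = []
        for v in sweep:
            m = dict(MUA)
            m["gm"] = v
            vals.append(interpolate_reflectance(micro_lut, q, m)[0])
        assert np.all(np.diff(vals) < 0)

    def test_midpoint_interpolation_error_below_mc_noise(
            self, homogeneous_model):
        # refine one axis: compare the interpolated midpoint against a
        # direct simulation at that midpoint
        probe = ring_probe(homogeneous_model, sds_list_cm=(0.8, 1.5),
                           ring_halfwidth_cm=0.1, acceptance_na=1.0)
        grid = MuspGrid(scalp=(8.0, 12.0, 16.0, 20.0), skull=(8.0, 20.0),
                        csf=(1.0, 3.7), gm=(8.0, 20.0))
        # homogeneous medium: tie all compartments to the scalp axis value
        results = []
        for row in grid.combos():
            musp = dict(zip(("scalp", "skull", "csf", "gm"), row))
            musp = {k: musp["scalp"] for k in musp}
            results.append(run_white_mc(
                homogeneous_model, probe, musp, 30_000, acceptance_na=1.0,
                rng=hash((row[0],)) % 2**31, path_cap_cm=80))
        table = LookupTable(grid=grid, results=results, acceptance_na=1.0,
                            base_seed=0)
        mua = {k: 0.15 for k in MUA}
        mid = {"scalp": 14.0, "skull": 14.0, "csf": 2.35, "gm": 14.0}
        interp = interpolate_reflectance(table, mid, mua)
        oracle = run_white_mc(homogeneous_model, probe,
                              {k: 14.0 for k in mid}, 120_000,
                              acceptance_na=1.0, rng=999, path_cap_cm=80)
        direct, sigma = reflectance_with_error(oracle, mua)
        for d in range(2):
            assert abs(interp[d] - direct[d]) < 5 * sigma[d] \
                + 0.03 * direct[d]


def _synthetic_pair(ratio, n_det=2, n_photons=1000, k=60, seed=0):
    """High/low-NA result pair where the low-NA subset keeps an exact
    fraction of the detected photons."""
    rng = np.random.default_rng(seed)
    det = rng.integers(0, n_det, k).astype(np.int32)
    pl = np.abs(rng.normal(2.0, 0.3, (k, 5)))
    ang = np.linspace(0, 1.0, k)
    high = WMCResult(det_id=det, pathlengths=pl, exit_angle=ang,
                     n_total=n_photons, n_detectors=n_det,
                     musp_combo={"scalp": 15.0, "skull": 15.0, "csf": 2.0,
                                 "gm": 15.0}, acceptance_na=1.0, seed=seed)
    keep = np.zeros(k, bool)
    for d in range(n_det):
        idx = np.nonzero(det == d)[0]
        keep[idx[:int(round(ratio * len(idx)))]] = True
    low = WMCResult(det_id=det[keep], pathlengths=pl[keep],
                    exit_angle=ang[keep], n_total=n_photons,
                    n_detectors=n_det, musp_combo=high.musp_combo,
                    acceptance_na=0.12, seed=seed)
    return high, low


class TestNAConversion:
    def test_constant_ratio_recovered(self):
        pairs = []
        for s in range(16):
            high, low = _synthetic_pair(0.4, seed=s)
            pairs.append((high, low, [np.zeros(5)]))
        model = fit_na_conversion(pairs)
        # query at the scale of the training features (detected fractions
        # of order 3e-2, ~30 counts); with zero absorption the ratio of
        # sums equals the count ratio up to per-pair rounding
        feats = np.array([[np.log(0.03), np.log(30.0), 0.0, 0.0,
                           15.0, 15.0]])
        assert model.predict_ratio(feats)[0] == pytest.approx(0.4,
                                                              abs=0.04)

    def test_identity_model_passthrough(self):
        model = NAConversionModel(coef=np.zeros(6), intercept=1.0, r2=1.0,
                                  residual_cv=0.0, n_obs=100)
        r = np.array([1e-3, 1e-5])
        feats = np.zeros((2, 6))
        assert np.allclose(apply_na_conversion(model, r, feats), r)

    def test_ratio_clipped_into_unit_interval(self):
        model = NAConversionModel(coef=np.zeros(6), intercept=1.7, r2=1.0,
                                  residual_cv=0.0, n_obs=100)
        out = model.predict_ratio(np.zeros((3, 6)))
        assert np.all(out <= 1.0)
        assert model.clip_events == 3

    def test_nonpositive_reflectance_rejected(self):
        model = NAConversionModel(coef=np.zeros(6), intercept=0.5, r2=1.0,
                                  residual_cv=0.0, n_obs=100)
        with pytest.raises(ValueError):
            apply_na_conversion(model, np.array([0.0]), np.zeros((1, 6)))

    def test_too_few_observations_rejected(self):
        high, low = _synthetic_pair(0.5)
        with pytest.raises(ValueError, match="30"):
            fit_na_conversion([(high, low, [np.zeros(5)])])

    def test_converted_reflectance_less_noisy_than_direct_low_na(
            self, micro_lut, homogeneous_model):
        # the acceleration rationale: wide-open collection plus the ratio
        # model yields a less noisy low-NA estimate than simulating the
        # narrow acceptance cone directly at the same photon budget
        rng = np.random.default_rng(3)
        mua_samples = sample_mua_combos(4, rng)
        pairs = [(res, res.filter_acceptance(0.12), list(mua_samples))
                 for res in micro_lut.results]
        model = fit_na_conversion(pairs)
        # physically the ratio is of order (NA/n)^2 ~ 0.7e-2
        mean_ratio = np.exp(np.mean(np.log(model.predict_ratio(
            np.column_stack([np.full(4, -6.0), np.full(4, 7.0),
                             mua_samples[:, 0], mua_samples[:, 1],
                             np.full(4, 15.0), np.full(4, 15.0)])))))
        assert 0.001 < mean_ratio < 0.05

        probe = ring_probe(homogeneous_model, sds_list_cm=(0.8, 1.5, 2.12),
                           ring_halfwidth_cm=0.1, acceptance_na=1.0)
        combo = {"scalp": 15.0, "skull": 15.0, "csf": 2.0, "gm": 15.0}
        mua5 = mua_samples[0]
        conv, direct = [], []
        for s in range(6):
            run = run_white_mc(homogeneous_model, probe, combo, 25_000,
                               acceptance_na=1.0, rng=200 + s,
                               path_cap_cm=80)
            r_hi = wmc_reflectance(run, mua5)
            feats = np.array([[np.log(max(r_hi[0], 1e-12)),
                               np.log(max(run.n_detected[0], 1)),
                               mua5[0], mua5[1], 15.0, 15.0]])
            conv.append(r_hi[0] * model.predict_ratio(feats)[0])
            direct.append(wmc_reflectance(
                run.filter_acceptance(0.12), mua5)[0])
        cv = lambda x: np.std(x) / np.mean(x)  # noqa: E731
        assert cv(conv) < cv(direct)

    def test_end_to_end_conversion_matches_direct_simulation(
            self, micro_lut, homogeneous_model):
        probe = ring_probe(homogeneous_model, sds_list_cm=(0.8, 1.5, 2.12),
                           ring_halfwidth_cm=0.1, acceptance_na=1.0)
        rng = np.random.default_rng(4)
        mua_samples = sample_mua_combos(5, rng)
        pairs = [(res, res.filter_acceptance(0.12), list(mua_samples))
                 for res in micro_lut.results]
        model = fit_na_conversion(pairs)
        # an independent run at a grid node, other seed
        node = 2
        combo = micro_lut.grid.combo_dict(node)
        other = run_white_mc(homogeneous_model, probe, combo, 50_000,
                             acceptance_na=1.0, rng=12345, path_cap_cm=80)
        mua5 = mua_samples[0]
        r_high, s_high = reflectance_with_error(other, mua5)
        r_low_direct, s_low = reflectance_with_error(
            other.filter_acceptance(0.12), mua5)
        feats = np.column_stack([
            np.log(r_high), np.log(np.maximum(other.n_detected, 1)),
            np.full(3, mua5[0]), np.full(3, mua5[1]),
            np.full(3, combo["scalp"]), np.full(3, combo["skull"])])
        converted = apply_na_conversion(model, r_high, feats)
        for d in range(2):  # shortest separations carry the statistics
            tol = 4 * (s_low[d] + s_high[d]) + 0.25 * r_low_direct[d]
            assert abs(converted[d] - r_low_direct[d]) < tol


class TestTrainingSet:
    def test_full_scale_row_count(self):
        assert training_row_count(2808, 3000, 3000) == 17_424_000

    def test_desk_scale_row_count(self):
        assert training_row_count(36, 50, 100) == 8_600

    def test_split_fractions_within_rounding(self, micro_lut):
        data = generate_training_set(micro_lut, n_mua=60, n_musp_extra=10,
                                     rng=5)
        n = data.n_rows
        counts = np.bincount(data.split, minlength=3)
        assert counts[0] == round(0.75 * n)
        assert counts[1] == round(0.10 * n)
        assert counts[2] == n - counts[0] - counts[1]

    def test_deterministic_given_seed(self, micro_lut):
        a = generate_training_set(micro_lut, n_mua=30, n_musp_extra=5,
                                  rng=8)
        b = generate_training_set(micro_lut, n_mua=30, n_musp_extra=5,
                                  rng=8)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.Y, b.Y)
        assert np.array_equal(a.split, b.split)

    def test_rows_strictly_positive(self, micro_lut):
        data = generate_training_set(micro_lut, n_mua=30, n_musp_extra=5,
                                     rng=9)
        assert np.all(data.Y > 0)
        assert data.X.shape == (data.n_rows, 8)

    def test_invalid_counts_rejected(self, micro_lut):
        with pytest.raises(ValueError):
            generate_training_set(micro_lut, n_mua=0)
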