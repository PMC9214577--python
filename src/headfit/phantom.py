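"""Three-layer phantom recovery study.

End-to-end validation of the inverse pipeline on a slab phantom whose
layers carry the optical roles of scalp, skull and (semi-infinite) gray
matter: multidistance reflectance spectra are generated with the direct
absorbing Monte Carlo engine from known ground-truth tissue parameters,
a lookup table and surrogate are built for the same geometry, and the
multi-start constrained fit recovers the layer optical properties.  The
headline figure of merit is the maximum relative error across the six
fitted OPs (mu_a and mu_s' of each layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chromophores import ChromophoreLibrary, OPRanges, TissueParams, \
    default_fit_wavelengths, params_to_op_spectra
from .forward import LookupTable, MuspGrid, generate_training_set
from .mc import run_white_mc
from .head_model import VoxelHeadModel, ring_probe
from .inverse import (OP_NAMES, FitTarget, ParamSpace, _OP_COLUMNS,
                      build_initial_pool, calibrate_spectra, fit_multistart,
                      select_solutions)
from .mc import run_absorbing_mc
from .surrogate import train_surrogate

__all__ = ["three_layer_phantom", "run_phantom_recovery", "PhantomRecovery"]

logger = logging.getLogger(__name__)


def three_layer_phantom(thicknesses_mm=(3.5, 5.0), dims=(120, 120, 60),
                        voxel_edge_mm: float = 0.93) -> VoxelHeadModel:
    """Flat slab with a scalp-like top layer, a skull-like middle layer and
    a semi-infinite gray-matter-like base (no CSF or white-matter layer —
    a physical layered phantom, not a head).  Default layer thicknesses
    follow bench-top layered phantoms (a few mm per layer), which places
    every layer within the well-sampled depth range of the probe."""
    t1, t2 = thicknesses_mm
    if t1 <= 0 or t2 <= 0:
        raise ValueError("layer thicknesses must be positive")
    nx, ny, nz = map(int, dims)
    z = (np.arange(nz) + 0.5) * voxel_edge_mm
    column = np.where(z <= t1, 1, np.where(z <= t1 + t2, 2, 4)).astype(
        np.int8)
    labels = np.broadcast_to(column, (nx, ny, nz)).copy()
    return VoxelHeadModel(labels=labels, voxel_edge_mm=voxel_edge_mm,
                          provenance={"generator": "three_layer_phantom",
                                      "thicknesses_mm": [t1, t2]})


@dataclass
class PhantomRecovery:
    """Outcome of one phantom recovery run."""

    truth_params: TissueParams
    truth_ops: np.ndarray          # (n_wavelengths, 8)
    fitted_ops: np.ndarray
    op_errors_percent: dict        # OP name -> |mean relative error| * 100
    max_error_percent: float
    spectral_error: float
    truth_spectral_error: float    # objective evaluated at the true params
    n_solutions: int
    wavelengths: np.ndarray
    target_reflectance: np.ndarray
    fitted_reflectance: np.ndarray
    surrogate_metrics: dict
    n_photons_node: int
    n_photons_target: int


def _fill_zero_readings(arr: np.ndarray, fallback: float) -> np.ndarray:
    """Replace zero-count reflectance readings by half the smallest
    positive reading of the same detector (last axis); Beer-Lambert
    weighted readings are legitimately far below one photon's worth, so a
    fixed count-based floor would destroy real data."""
    flat = arr.reshape(-1, arr.shape[-1])
    pos = np.where(flat > 0, flat, np.inf)
    fill = 0.5 * pos.min(axis=0)
    fill = np.where(np.isfinite(fill), fill, fallback)
    out = np.where(flat > 0, flat, fill[None])
    return out.reshape(arr.shape)


def build_phantom_lookup(model, probe, grid: MuspGrid, n_photons: int,
                         base_seed: int, path_cap_cm: float = 100.0,
                         progress: bool = False) -> LookupTable:
    """Lookup table for a CSF-free phantom.

    The phantom contains no CSF voxels, so reflectance is exactly constant
    along the CSF mu_s' axis: only the unique (scalp, skull, GM)
    combinations are simulated and each result is shared by all CSF nodes.
    This halves the simulation cost with zero approximation error (the
    interpolant is constant along that axis)."""
    from .chromophores import LABELS
    if np.any(model.labels == LABELS["csf"]):
        raise ValueError("model contains CSF voxels; use "
                         "build_lookup_table")
    n_s, n_k, n_c, n_g = grid.shape
    unique = {}
    idx = 0
    for i_s, s in enumerate(grid.scalp):
        for i_k, k in enumerate(grid.skull):
            for i_g, g in enumerate(grid.gm):
                musp = {"scalp": float(s), "skull": float(k),
                        "csf": float(grid.csf[0]), "gm": float(g)}
                res = run_white_mc(model, probe, musp, n_photons,
                                   acceptance_na=probe.acceptance_na,
                                   rng=(base_seed * 2654435761 + 7 + idx)
                                   % (2 ** 31),
                                   path_cap_cm=path_cap_cm)
                unique[(i_s, i_k, i_g)] = res
                idx += 1
                if progress:
                    logger.info("phantom node %d/%d done", idx,
                                n_s * n_k * n_g)
    results = []
    from dataclasses import replace as _replace
    for i_s in range(n_s):
        for i_k in range(n_k):
            for i_c in range(n_c):
                for i_g in range(n_g):
                    res = unique[(i_s, i_k, i_g)]
                    combo = dict(res.musp_combo)
                    combo["csf"] = float(grid.csf[i_c])
                    results.append(_replace(res, musp_combo=combo))
    return LookupTable(grid=grid, results=results,
                       acceptance_na=probe.acceptance_na,
                       base_seed=base_seed,
                       model_fingerprint=model.fingerprint(),
                       probe_fingerprint=probe.fingerprint())


def default_phantom_truth() -> TissueParams:
    """Ground-truth layer parameters of the synthetic phantom: mid-range
    physiological values, fixed by design (a physical phantom has known,
    controlled OPs; randomness belongs to the photon transport and the
    fitting pipeline, not to the phantom)."""
    return TissueParams()


def run_phantom_recovery(seed: int = 1, n_photons_node: int = 160_000,
                         n_photons_target: int = 150_000,
                         n_photons_cal: int = 100_000,
                         n_cal_phantoms: int = 6,
                         n_mua: int = 300, n_musp_extra: int = 50,
                         pool_size: int = 3000, n_starts: int = 20,
                         max_iter: int = 300,
                         fit_detectors=(0, 1, 2, 3),
                         tiebreak_detectors=(4, 5),
                         wavelengths=None, path_cap_cm: float = 100.0,
                         truth: TissueParams | None = None,
                         grid: MuspGrid | None = None,
                         lib: ChromophoreLibrary | None = None,
                         prebuilt: dict | None = None,
                         progress: bool = False) -> PhantomRecovery:
    """Run the full desk-scale phantom validation.

    All randomness (photon transport, training-row sampling, network
    initialization, pool draws) derives from ``seed``.  The pipeline
    mirrors the in-vivo procedure: the raw target spectra are first
    calibrated against a set of known calibration phantoms simulated on
    both sides (direct MC as the "measurement", surrogate as the model),
    which absorbs the per-detector level bias of the forward chain exactly
    as the instrument calibration does; the calibrated spectra are then
    fitted with the multi-start constrained optimizer.  With the thin
    phantom layers every layer is probed by the four shortest separations,
    which carry the soundest photon statistics; the two longest act as tie
    breakers.  Detector acceptance is the wide-open mode on both sides, so
    no NA conversion enters this study.

    ``prebuilt`` may supply {"model", "probe", "table", "surrogate"} to
    reuse an existing forward bundle; the seed then drives only the
    target, calibration and fitting stages.
    """
    lib = lib or ChromophoreLibrary.from_tsv()
    ranges = OPRanges.default()
    grid = grid or MuspGrid.desk_scale()
    lam = default_fit_wavelengths() if wavelengths is None \
        else np.asarray(wavelengths, float)
    truth = truth or default_phantom_truth()
    ss = np.random.SeedSequence(seed)
    (seed_lut, seed_target, seed_train, seed_net, seed_pool,
     seed_cal) = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(6)]

    if prebuilt is not None:
        model = prebuilt["model"]
        probe = prebuilt["probe"]
    else:
        model = three_layer_phantom()
        # annular detectors (may overlap, each tallies independently); the
        # long-separation rings are widest because the gray-matter signal
        # lives there and its photon flux is lowest
        halfwidths = (0.1, 0.2, 0.3, 0.3, 0.3, 0.5)
        probe = ring_probe(model, ring_halfwidth_cm=halfwidths,
                           acceptance_na=1.0)

    # --- target spectra from the absorbing-MC oracle ----------------------
    truth_spec = params_to_op_spectra(truth, lib, ranges, lam)
    truth_ops = truth_spec.op_matrix()
    target = np.empty((len(lam), len(probe.detectors)))
    for i in range(len(lam)):
        mua = {"scalp": truth_ops[i, 0], "skull": truth_ops[i, 1],
               "csf": truth_ops[i, 2], "gm": truth_ops[i, 3]}
        musp = {"scalp": truth_ops[i, 4], "skull": truth_ops[i, 5],
                "csf": truth_ops[i, 6], "gm": truth_ops[i, 7]}
        target[i] = run_absorbing_mc(model, probe, mua, musp,
                                     n_photons_target,
                                     rng=(seed_target + 131 * i) % 2 ** 31,
                                     path_cap_cm=path_cap_cm)
        if progress:
            logger.info("target %d/%d done", i + 1, len(lam))
    # zero-count readings (possible at the longest separation) stay
    # strictly positive without inventing signal above what was observed
    target = _fill_zero_readings(target, 0.5 / n_photons_target)

    # --- forward model: lookup table -> training set -> surrogate ---------
    if prebuilt is not None:
        table = prebuilt["table"]
        model_fwd = prebuilt["surrogate"]
    else:
        table = build_phantom_lookup(model, probe, grid, n_photons_node,
                                     base_seed=seed_lut,
                                     path_cap_cm=path_cap_cm,
                                     progress=progress)
        data = generate_training_set(table, n_mua=n_mua,
                                     n_musp_extra=n_musp_extra,
                                     rng=seed_train)
        model_fwd = train_surrogate(data, seed=seed_net)

    # --- calibration against known phantoms -------------------------------
    space = ParamSpace(lib=lib, ranges=ranges)
    cal_rng = np.random.default_rng(seed_cal)
    cal_lam = np.linspace(lam[0], lam[-1], 4)
    cal_vecs = space.sample_valid(n_cal_phantoms, cal_rng, cal_lam)
    cal_ops = space.op_matrix_batch(cal_vecs, cal_lam)
    measured = np.empty((n_cal_phantoms, len(cal_lam),
                         len(probe.detectors)))
    for p in range(n_cal_phantoms):
        for i in range(len(cal_lam)):
            mua = dict(zip(("scalp", "skull", "csf", "gm"),
                           cal_ops[p, i, :4]))
            musp = dict(zip(("scalp", "skull", "csf", "gm"),
                            cal_ops[p, i, 4:]))
            measured[p, i] = run_absorbing_mc(
                model, probe, mua, musp, n_photons_cal,
                rng=(seed_cal + 977 * (p * len(cal_lam) + i) + 1) % 2 ** 31,
                path_cap_cm=path_cap_cm)
        if progress:
            logger.info("calibration phantom %d/%d done", p + 1,
                        n_cal_phantoms)
    measured = _fill_zero_readings(measured, 0.5 / n_photons_cal)
    simulated = model_fwd.predict_reflectance(
        cal_ops.reshape(-1, 8), warn_out_of_range=False).reshape(
            measured.shape)

    # --- inverse fit -------------------------------------------------------
    pool = build_initial_pool(model_fwd, space, n=pool_size,
                              wavelengths=lam, rng=seed_pool)
    # level (wavelength-pooled) calibration as in the in-vivo procedure;
    # the spectral variant transfers OP-dependent chain error from the
    # calibration phantoms to the target and performs worse here
    fit_target = calibrate_spectra(measured, simulated, target, lam,
                                   tuple(fit_detectors),
                                   tuple(tiebreak_detectors))
    results = fit_multistart(fit_target, model_fwd, pool, space=space,
                             n_starts=n_starts, max_iter=max_iter)
    solset = select_solutions(results)
    best = solset.solutions[0]

    # diagnostic: the objective at the true parameters separates an
    # optimizer failure (best error well below truth error) from an
    # information limit (several basins at the noise floor)
    from .inverse import spectral_error
    truth_R = model_fwd.predict_reflectance(truth_ops,
                                            warn_out_of_range=False)
    truth_err = spectral_error(truth_R, fit_target.reflectance,
                               list(fit_detectors))

    errors = {}
    for name in OP_NAMES:
        col = _OP_COLUMNS[name]
        rel = (best.op_spectra[:, col] - truth_ops[:, col]) \
            / truth_ops[:, col]
        errors[name] = float(abs(np.mean(rel)) * 100.0)
    fitted_R = model_fwd.predict_reflectance(best.op_spectra,
                                             warn_out_of_range=False)
    return PhantomRecovery(
        truth_params=truth, truth_ops=truth_ops,
        fitted_ops=best.op_spectra, op_errors_percent=errors,
        max_error_percent=max(errors.values()),
        spectral_error=best.error_fit,
        truth_spectral_error=float(truth_err),
        n_solutions=len(solset.solutions),
        wavelengths=lam, target_reflectance=fit_target.reflectance,
        fitted_reflectance=fitted_R,
        surrogate_metrics={k: np.asarray(v).tolist()
                           for k, v in model_fwd.metrics.items()},
        n_photons_node=n_photons_node, n_photons_target=n_photons_target)
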