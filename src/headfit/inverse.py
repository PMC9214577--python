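"""Iterative curve fitting of multidistance reflectance spectra.

The inverse problem estimates the variable tissue parameters of scalp,
skull and gray matter (total hemoglobin, oxygen saturation, melanin
fraction, scattering power-law amplitude and exponent — 13 scalars) by
minimizing the RMS percent spectral error

    err = sqrt( sum_d sum_i (Rs(d,i)/Rm(d,i) - 1)^2 / (nd * n_lambda) )

between surrogate-simulated spectra Rs and the calibrated target spectra
Rm over a fixed wavelength set.  Fitting is repeated from the 20 best
starting points drawn from a presimulated random pool to handle local
minima, under bound constraints plus the nonlinear constraint that the
derived optical properties stay inside their admissible ranges at every
fitted wavelength.  When several fits end within the measurement noise
level (2 % spectral error) of the best one, detectors excluded from the
fit act as tie breakers; surviving ties are reported as multiple
solutions.

The scattering power law is fitted as (mu_s'(800 nm), K) rather than
(A, K); A = mu_s'(800) * 800^K.  The two parameterizations are equivalent
but the former keeps optimizer scaling uniform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .chromophores import (ChromophoreLibrary, OPRanges, TissueParams,
                           TissueRecord, default_fit_wavelengths)
from .surrogate import SurrogateModel

__all__ = [
    "FitTarget",
    "CalibrationModel",
    "FitResult",
    "SolutionSet",
    "ParamSpace",
    "InitialPool",
    "spectral_error",
    "calibrate_spectra",
    "build_initial_pool",
    "fit_multistart",
    "select_solutions",
    "scan_detector_combinations",
]

logger = logging.getLogger(__name__)

#: the six reported optical properties, in display order
OP_NAMES = ("mua_scalp", "musp_scalp", "mua_skull", "musp_skull",
            "mua_gm", "musp_gm")

#: columns of the 8-wide OP matrix for each reported OP
_OP_COLUMNS = {"mua_scalp": 0, "mua_skull": 1, "mua_csf": 2, "mua_gm": 3,
               "musp_scalp": 4, "musp_skull": 5, "musp_csf": 6, "musp_gm": 7}


# ---------------------------------------------------------------------------
# spectral error (the objective)
# ---------------------------------------------------------------------------

def spectral_error(Rs, Rm, detectors=None) -> float:
    """RMS percent error between simulated and measured spectra.

    ``Rs`` and ``Rm`` are (n_wavelengths, n_detectors) arrays;
    ``detectors`` selects columns (0-based) — default all.
    """
    Rs = np.asarray(Rs, float)
    Rm = np.asarray(Rm, float)
    if Rs.shape != Rm.shape:
        raise ValueError("shape mismatch between simulated and measured")
    if detectors is not None:
        Rs = Rs[:, list(detectors)]
        Rm = Rm[:, list(detectors)]
    if np.any(Rm <= 0):
        raise ValueError("measured reflectance must be positive")
    return float(np.sqrt(np.mean((Rs / Rm - 1.0) ** 2)))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Per-detector linear map from measured to absolute reflectance."""

    slope: np.ndarray
    intercept: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.slope <= 0):
            raise ValueError("calibration mapping must be strictly "
                             "increasing (positive slopes)")

    def apply(self, measured: np.ndarray) -> np.ndarray:
        return measured * self.slope + self.intercept


@dataclass(frozen=True)
class FitTarget:
    """Calibrated target spectra plus the detector split."""

    wavelengths: np.ndarray
    reflectance: np.ndarray        # (n_wavelengths, n_detectors)
    fit_detectors: tuple
    tiebreak_detectors: tuple = ()

    def __post_init__(self) -> None:
        if set(self.fit_detectors) & set(self.tiebreak_detectors):
            raise ValueError("fit and tie-breaker detector sets overlap")
        if np.any(np.asarray(self.reflectance) <= 0):
            raise ValueError("target reflectance must be positive")
        if len(self.wavelengths) != len(self.reflectance):
            raise ValueError("wavelength/reflectance length mismatch")


def calibrate_spectra(measured_phantoms, simulated_phantoms, raw_target,
                      wavelengths, fit_detectors,
                      tiebreak_detectors=()) -> FitTarget:
    """Fit the per-detector calibration regression on phantom pairs and
    apply it to the raw target spectra.

    ``measured_phantoms`` and ``simulated_phantoms`` are
    (n_phantoms, n_wavelengths, n_detectors) stacks; ``raw_target`` is
    either one spectrum (n_wavelengths, n_detectors) or a stack of
    repeated measurements, which are averaged first.
    """
    meas = np.asarray(measured_phantoms, float)
    sim = np.asarray(simulated_phantoms, float)
    if meas.shape != sim.shape or meas.ndim != 3:
        raise ValueError("phantom stacks must share shape "
                         "(n_phantoms, n_wavelengths, n_detectors)")
    if meas.shape[0] < 2:
        raise ValueError("need at least two calibration phantoms")
    nd = meas.shape[2]
    slope = np.empty(nd)
    intercept = np.empty(nd)
    for d in range(nd):
        x = meas[:, :, d].ravel()
        y = sim[:, :, d].ravel()
        if np.ptp(x) < 1e-15 * max(abs(x).max(), 1e-300):
            raise ValueError(f"degenerate calibration for detector {d}: "
                             "identical phantom intensities")
        A = np.column_stack([x, np.ones_like(x)])
        (slope[d], intercept[d]), *_ = np.linalg.lstsq(A, y, rcond=None)
    cal = CalibrationModel(slope=slope, intercept=intercept)
    target = np.asarray(raw_target, float)
    if target.ndim == 3:
        target = target.mean(axis=0)
    out = cal.apply(target)
    # a negative intercept can push a near-noise-floor reading below zero;
    # keep it at a vanishing positive level instead
    out = np.maximum(out, 1e-9 * out.max())
    return FitTarget(wavelengths=np.asarray(wavelengths, float),
                     reflectance=out,
                     fit_detectors=tuple(fit_detectors),
                     tiebreak_detectors=tuple(tiebreak_detectors))


def calibrate_spectra_spectral(measured_phantoms, simulated_phantoms,
                               cal_wavelengths, raw_target,
                               target_wavelengths, fit_detectors,
                               tiebreak_detectors=(),
                               smooth: bool = True) -> FitTarget:
    """Per-detector spectral calibration regression.

    A broadband instrument's response varies with wavelength; here the
    per-detector calibration map sim = a(lam)*meas + b(lam) carries
    slope and intercept curves.  With ``smooth=True`` (default) a(lam)
    and b(lam) are linear in wavelength, fitted on all
    (phantom, calibration-wavelength) points jointly — robust with a
    handful of phantoms; with ``smooth=False`` each calibration
    wavelength is fitted independently and the curves are interpolated
    (needs many phantoms per wavelength to stay noise-free).  Shapes:
    ``measured_phantoms`` and ``simulated_phantoms`` are
    (n_phantoms, n_cal_wavelengths, n_detectors); ``raw_target`` is
    (n_target_wavelengths, n_detectors) or a stack of repeats.
    """
    meas = np.asarray(measured_phantoms, float)
    sim = np.asarray(simulated_phantoms, float)
    cal_lam = np.asarray(cal_wavelengths, float)
    lam = np.asarray(target_wavelengths, float)
    if meas.shape != sim.shape or meas.ndim != 3 \
            or meas.shape[1] != len(cal_lam):
        raise ValueError("phantom stacks must share shape "
                         "(n_phantoms, n_cal_wavelengths, n_detectors)")
    if meas.shape[0] < 2:
        raise ValueError("need at least two calibration phantoms")
    n_p, n_l, nd = meas.shape
    lam0 = cal_lam.mean()
    s_t = np.empty((len(lam), nd))
    b_t = np.empty((len(lam), nd))
    for d in range(nd):
        x = meas[:, :, d]
        y = sim[:, :, d]
        if np.ptp(x) < 1e-15 * max(np.abs(x).max(), 1e-300):
            raise ValueError(f"degenerate calibration for detector {d}: "
                             "identical phantom intensities")
        if smooth:
            dl = np.broadcast_to(cal_lam - lam0, x.shape).ravel()
            xf = x.ravel()
            A = np.column_stack([xf, xf * dl, np.ones_like(xf), dl])
            coef, *_ = np.linalg.lstsq(A, y.ravel(), rcond=None)
            s = coef[0] + coef[1] * (lam - lam0)
            b = coef[2] + coef[3] * (lam - lam0)
        else:
            slope = np.empty(n_l)
            inter = np.empty(n_l)
            for i in range(n_l):
                if np.ptp(x[:, i]) < 1e-15 * max(np.abs(x[:, i]).max(),
                                                 1e-300):
                    raise ValueError(
                        f"degenerate calibration for detector {d} at "
                        f"{cal_lam[i]:.0f} nm")
                A = np.column_stack([x[:, i], np.ones(n_p)])
                (slope[i], inter[i]), *_ = np.linalg.lstsq(
                    A, y[:, i], rcond=None)
            s = np.interp(lam, cal_lam, slope)
            b = np.interp(lam, cal_lam, inter)
        if np.any(s <= 0):
            raise ValueError("calibration mapping must be strictly "
                             "increasing (positive slopes)")
        s_t[:, d] = s
        b_t[:, d] = b
    target = np.asarray(raw_target, float)
    if target.ndim == 3:
        target = target.mean(axis=0)
    out = target * s_t + b_t
    out = np.maximum(out, 1e-9 * out.max())
    return FitTarget(wavelengths=lam, reflectance=out,
                     fit_detectors=tuple(fit_detectors),
                     tiebreak_detectors=tuple(tiebreak_detectors))


# ---------------------------------------------------------------------------
# parameter space
# ---------------------------------------------------------------------------

def _default_bounds() -> dict:
    # (low, high) per free parameter; tHB in M, musp800 in 1/cm
    return {
        "scalp_tHB": (5e-6, 2.6e-4), "scalp_StO2": (0.0, 1.0),
        "scalp_Cmel": (0.0, 1.5e-3),
        "scalp_musp800": (5.0, 35.0), "scalp_K": (0.0, 3.0),
        "skull_tHB": (2e-6, 2.0e-4), "skull_StO2": (0.0, 1.0),
        "skull_musp800": (5.0, 35.0), "skull_K": (0.0, 3.0),
        "gm_tHB": (5e-6, 2.2e-4), "gm_StO2": (0.0, 1.0),
        "gm_musp800": (5.0, 35.0), "gm_K": (0.0, 3.0),
    }


@dataclass
class ParamSpace:
    """Vectorization of the 13 free tissue parameters with box bounds.

    Internally the optimizer works on the unit cube; ``to_params`` /
    ``from_params`` convert between vectors and :class:`TissueParams`.
    """

    lib: ChromophoreLibrary
    ranges: OPRanges = field(default_factory=OPRanges.default)
    bounds: dict = field(default_factory=_default_bounds)

    def __post_init__(self) -> None:
        self.names = tuple(self.bounds)
        self.lo = np.array([self.bounds[n][0] for n in self.names])
        self.hi = np.array([self.bounds[n][1] for n in self.names])

    @property
    def n_params(self) -> int:
        return len(self.names)

    def to_params(self, vec) -> TissueParams:
        v = dict(zip(self.names, np.asarray(vec, float)))
        scalp = TissueRecord(
            tHB=v["scalp_tHB"], StO2=v["scalp_StO2"],
            A=1.0, K=v["scalp_K"], C_melanin=v["scalp_Cmel"],
            C_water=0.75, C_collagen=0.02,
        ).with_musp_at(v["scalp_musp800"], v["scalp_K"])
        skull = TissueRecord(
            tHB=v["skull_tHB"], StO2=v["skull_StO2"], A=1.0, K=v["skull_K"],
        ).with_musp_at(v["skull_musp800"], v["skull_K"])
        gm = TissueRecord(
            tHB=v["gm_tHB"], StO2=v["gm_StO2"], A=1.0, K=v["gm_K"],
            C_water=0.75,
        ).with_musp_at(v["gm_musp800"], v["gm_K"])
        return TissueParams(scalp=scalp, skull=skull, gm=gm)

    def from_params(self, params: TissueParams) -> np.ndarray:
        out = []
        for name in self.names:
            tissue, attr = name.split("_", 1)
            rec: TissueRecord = getattr(params, tissue)
            if attr == "musp800":
                out.append(rec.A * 800.0 ** (-rec.K))
            elif attr == "Cmel":
                out.append(rec.C_melanin)
            else:
                out.append(getattr(rec, attr))
        return np.array(out)

    # --- vectorized OP evaluation -----------------------------------------

    def _lib_cache(self, wavelengths) -> dict:
        lam = np.asarray(wavelengths, float)
        key = lam.tobytes()
        cache = getattr(self, "_lc", None)
        if cache is None or cache[0] != key:
            cache = (key, {
                "eps_HbO": self.lib.sample("eps_HbO", lam),
                "eps_Hb": self.lib.sample("eps_Hb", lam),
                "mua_water": self.lib.sample("mua_water", lam),
                "mua_collagen": self.lib.sample("mua_collagen", lam),
                "mua_melanin": self.lib.sample("mua_melanin", lam),
                "mua_CSF": self.lib.sample("mua_CSF", lam),
                "musp_CSF": self.lib.sample("musp_CSF", lam),
                "lam": lam,
            })
            self._lc = cache
        return cache[1]

    def op_matrix_batch(self, vecs, wavelengths) -> np.ndarray:
        """(n, n_wavelengths, 8) forward-model inputs for parameter-vector
        rows, without per-row Python overhead."""
        V = np.atleast_2d(np.asarray(vecs, float))
        c = self._lib_cache(wavelengths)
        lam = c["lam"]
        idx = {n: i for i, n in enumerate(self.names)}

        def col(name):
            return V[:, idx[name]][:, None]

        out = np.empty((len(V), len(lam), 8))
        for j, tissue in enumerate(("scalp", "skull", "gm")):
            eps = (c["eps_HbO"] * col(f"{tissue}_StO2")
                   + c["eps_Hb"] * (1.0 - col(f"{tissue}_StO2")))
            mua = 2.303 * eps * col(f"{tissue}_tHB")
            if tissue == "scalp":
                mua = mua + 0.75 * c["mua_water"] + 0.02 * c["mua_collagen"] \
                    + col("scalp_Cmel") * c["mua_melanin"]
            elif tissue == "gm":
                mua = mua + 0.75 * c["mua_water"]
            out[:, :, _OP_COLUMNS[f"mua_{tissue}"]] = mua
            musp = col(f"{tissue}_musp800") \
                * (lam / 800.0) ** (-col(f"{tissue}_K"))
            out[:, :, _OP_COLUMNS[f"musp_{tissue}"]] = musp
        out[:, :, _OP_COLUMNS["mua_csf"]] = c["mua_CSF"]
        out[:, :, _OP_COLUMNS["musp_csf"]] = c["musp_CSF"]
        return out

    def constraint_margins(self, vec, wavelengths) -> np.ndarray:
        """Nonnegative iff every derived OP stays inside its range at every
        fitted wavelength (12 values: min/max for mu_a and mu_s' of scalp,
        skull, gray matter)."""
        ops = self.op_matrix_batch(vec[None], wavelengths)[0]
        margins = []
        for tissue in ("scalp", "skull", "gm"):
            for qty in ("mua", "musp"):
                lo, hi = getattr(self.ranges, qty)[tissue]
                vals = ops[:, _OP_COLUMNS[f"{qty}_{tissue}"]]
                margins.append(vals.min() - lo)
                margins.append(hi - vals.max())
        return np.array(margins)

    def sample_valid(self, n: int, rng: np.random.Generator,
                     wavelengths) -> np.ndarray:
        """Uniform draws over the box, rejecting vectors whose OPs leave
        the admissible ranges at any wavelength."""
        out = []
        need = n
        while need > 0:
            cand = rng.uniform(self.lo, self.hi, size=(max(2 * need, 64),
                                                       self.n_params))
            ops = self.op_matrix_batch(cand, wavelengths)
            ok = np.ones(len(cand), bool)
            for tissue in ("scalp", "skull", "gm"):
                for qty in ("mua", "musp"):
                    lo, hi = getattr(self.ranges, qty)[tissue]
                    vals = ops[:, :, _OP_COLUMNS[f"{qty}_{tissue}"]]
                    ok &= (vals.min(axis=1) >= lo) & (vals.max(axis=1) <= hi)
            cand = cand[ok]
            out.append(cand[:need])
            need -= len(cand[:need])
        return np.vstack(out)


# ---------------------------------------------------------------------------
# initial pool and multistart fitting
# ---------------------------------------------------------------------------

@dataclass
class InitialPool:
    """Random valid parameter vectors with presimulated spectra."""

    vectors: np.ndarray            # (n, 13)
    spectra: np.ndarray            # (n, n_wavelengths, n_detectors)
    wavelengths: np.ndarray
    seed: int


def build_initial_pool(surrogate: SurrogateModel, space: ParamSpace,
                       n: int = 5000, wavelengths=None,
                       rng: np.random.Generator | int = 0) -> InitialPool:
    """Draw ``n`` valid random parameter sets and presimulate their spectra
    once with the surrogate."""
    if n < 20:
        raise ValueError("pool size must be >= 20")
    lam = default_fit_wavelengths() if wavelengths is None \
        else np.asarray(wavelengths, float)
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    seed = int(rng.integers(2 ** 31))
    rng = np.random.default_rng(seed)
    vecs = space.sample_valid(n, rng, lam)
    ops = space.op_matrix_batch(vecs, lam)
    R = surrogate.predict_reflectance(ops.reshape(-1, 8),
                                      warn_out_of_range=False)
    return InitialPool(vectors=vecs,
                       spectra=R.reshape(n, len(lam), -1),
                       wavelengths=lam, seed=seed)


@dataclass
class FitResult:
    """One converged (or stopped) start of the iterative curve fit."""

    params: TissueParams
    vector: np.ndarray
    op_spectra: np.ndarray         # (n_wavelengths, 8)
    error_fit: float
    error_tiebreak: float
    start_index: int
    n_iterations: int
    converged: bool

    def op_spectrum(self, name: str) -> np.ndarray:
        return self.op_spectra[:, _OP_COLUMNS[name]]


@dataclass
class SolutionSet:
    """Survivors of the two-stage multiple-solution selection."""

    solutions: list
    multiple: bool
    threshold: float
    stage1_count: int


def fit_multistart(target: FitTarget, surrogate: SurrogateModel,
                   pool: InitialPool, space: ParamSpace | None = None,
                   n_starts: int = 20, max_iter: int = 2000,
                   lib: ChromophoreLibrary | None = None) -> list:
    """Constrained multi-start curve fit.

    The ``n_starts`` pool members with the smallest spectral error against
    the target (on the fitted detectors) seed independent SLSQP runs on
    the unit-cube-scaled parameters with the OP-range nonlinear
    constraint.  Results are sorted by fitted-detector spectral error.
    """
    if space is None:
        space = ParamSpace(lib=lib or ChromophoreLibrary.from_tsv())
    if len(pool.vectors) < n_starts:
        raise ValueError("pool smaller than the number of starts")
    lam = target.wavelengths
    if not np.allclose(pool.wavelengths, lam):
        raise ValueError("pool was presimulated on different wavelengths")
    fit_det = list(target.fit_detectors)
    tie_det = list(target.tiebreak_detectors)
    Rm = target.reflectance

    pool_err = np.sqrt(np.mean(
        (pool.spectra[:, :, fit_det] / Rm[None, :, fit_det] - 1.0) ** 2,
        axis=(1, 2)))
    order = np.argsort(pool_err)[:n_starts]

    span = space.hi - space.lo

    def unscale(x):
        return space.lo + x * span

    def objective(x):
        ops = space.op_matrix_batch(unscale(x)[None], lam)[0]
        Rs = surrogate.predict_reflectance(ops, warn_out_of_range=False)
        return np.sqrt(np.mean((Rs[:, fit_det] / Rm[:, fit_det] - 1.0) ** 2))

    def constraints(x):
        return space.constraint_margins(unscale(x), lam)

    results = []
    failures = []
    for start in order:
        x0 = (pool.vectors[start] - space.lo) / span
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(objective, x0, method="SLSQP",
                           bounds=[(0.0, 1.0)] * space.n_params,
                           constraints=[{"type": "ineq",
                                         "fun": constraints}],
                           options={"maxiter": max_iter, "ftol": 1e-10})
        vec = unscale(np.clip(res.x, 0.0, 1.0))
        ops = space.op_matrix_batch(vec[None], lam)[0]
        Rs = surrogate.predict_reflectance(ops, warn_out_of_range=False)
        err_fit = spectral_error(Rs, Rm, fit_det)
        err_tie = spectral_error(Rs, Rm, tie_det) if tie_det else np.nan
        fr = FitResult(
            params=space.to_params(vec), vector=vec, op_spectra=ops,
            error_fit=err_fit, error_tiebreak=err_tie,
            start_index=int(start), n_iterations=int(res.nit),
            converged=bool(res.success))
        (results if np.isfinite(err_fit) else failures).append(fr)
    if not results:
        raise RuntimeError("all starts failed to converge; last diagnostics: "
                           f"{failures[-1] if failures else 'none'}")
    results.sort(key=lambda r: r.error_fit)
    return results


def select_solutions(results, threshold: float = 0.02) -> SolutionSet:
    """Two-stage multiple-solution selection.

    Stage 1 keeps results whose fitted-detector error is within
    ``threshold`` (absolute, in spectral-error units) of the smallest;
    stage 2 keeps, among those, results whose tie-breaker error is within
    ``threshold`` of the stage-1 minimum of that quantity.  Two or more
    survivors raise the multiplicity flag.
    """
    if not results:
        raise ValueError("no fit results")
    best = min(r.error_fit for r in results)
    stage1 = [r for r in results if r.error_fit <= best + threshold]
    if all(np.isnan(r.error_tiebreak) for r in stage1):
        logger.warning("no tie-breaker detectors configured; stage 2 "
                       "skipped")
        survivors = sorted(stage1, key=lambda r: r.error_fit)
    else:
        best_tie = min(r.error_tiebreak for r in stage1)
        survivors = sorted(
            [r for r in stage1 if r.error_tiebreak <= best_tie + threshold],
            key=lambda r: r.error_tiebreak)
    return SolutionSet(solutions=survivors, multiple=len(survivors) >= 2,
                       threshold=threshold, stage1_count=len(stage1))


def scan_detector_combinations(raw_reflectance, wavelengths, combinations,
                               surrogate: SurrogateModel, pool: InitialPool,
                               space: ParamSpace, n_detectors: int = 6,
                               error_threshold: float = 0.15,
                               n_starts: int = 20,
                               max_iter: int = 2000) -> dict:
    """Fit each detector combination and choose the largest one whose mean
    fitted spectral error stays below the threshold.

    ``combinations`` is an iterable of tuples of 0-based detector indices;
    the complement of each combination serves as its tie-breaker set.
    Returns the chosen combination, per-combination solution sets and
    errors.
    """
    outcomes = {}
    for combo in combinations:
        tie = tuple(d for d in range(n_detectors) if d not in combo)
        target = FitTarget(wavelengths=np.asarray(wavelengths, float),
                           reflectance=np.asarray(raw_reflectance, float),
                           fit_detectors=tuple(combo),
                           tiebreak_detectors=tie)
        results = fit_multistart(target, surrogate, pool, space=space,
                                 n_starts=n_starts, max_iter=max_iter)
        sol = select_solutions(results)
        outcomes[tuple(combo)] = {
            "solutions": sol,
            "error": float(np.mean([r.error_fit for r in sol.solutions])),
        }
    eligible = [c for c, o in outcomes.items()
                if o["error"] < error_threshold]
    chosen = max(eligible, key=len) if eligible else None
    return {"chosen": chosen, "outcomes": outcomes,
            "threshold": error_threshold}
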