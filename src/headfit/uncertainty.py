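"""Uncertainty quantification for the fitted optical properties.

Generates synthetic noisy test spectra whose per-detector coefficients of
variation match those measured on repeated in-vivo acquisitions, compiles
relative-error distributions and empirical confidence intervals of the six
reported OPs, and runs the supporting analyses: reflectance sensitivity per
source-detector separation and the rank validation that justifies picking
the fit with the smallest spectral error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inverse import OP_NAMES, ParamSpace, _OP_COLUMNS
from .surrogate import SurrogateModel

__all__ = [
    "NoiseModel",
    "TestSpectraSet",
    "ErrorDistribution",
    "generate_test_spectra",
    "compile_confidence_intervals",
    "sensitivity_analysis",
    "rank_validation",
]

logger = logging.getLogger(__name__)

#: measured per-detector CVs of repeated reflectance acquisitions (%)
DEFAULT_NOISE_CV = (3.0, 4.2, 5.1, 5.2, 5.4, 12.1)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative reflectance noise with per-detector CV (percent).

    Factors are lognormal with unit mean; by default independent across
    detectors and wavelengths, optionally fully correlated across
    wavelengths within a detector (emulating probe-coupling drift).
    """

    cv_percent: tuple = DEFAULT_NOISE_CV
    correlated_across_wavelengths: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.cv_percent) < 0):
            raise ValueError("noise CVs must be >= 0")

    def factors(self, n_wavelengths: int, rng: np.random.Generator
                ) -> np.ndarray:
        cv = np.asarray(self.cv_percent, float) / 100.0
        sigma = np.sqrt(np.log1p(cv ** 2))
        mu = -0.5 * sigma ** 2  # unit-mean lognormal
        if self.correlated_across_wavelengths:
            z = rng.standard_normal(len(cv))[None, :]
        else:
            z = rng.standard_normal((n_wavelengths, len(cv)))
        return np.exp(mu + sigma * z)


@dataclass
class TestSpectraSet:
    """Ground-truthed synthetic targets with noisy replicates."""

    vectors: np.ndarray            # (n_param, 13) true parameter vectors
    truth_ops: np.ndarray          # (n_param, n_wavelengths, 8)
    noiseless: np.ndarray          # (n_param, n_wavelengths, n_detectors)
    noisy: np.ndarray              # (n_param, n_noise, n_wl, n_det)
    wavelengths: np.ndarray
    seed: int
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def n_replicates(self) -> int:
        return self.noisy.shape[0] * self.noisy.shape[1]


def generate_test_spectra(surrogate: SurrogateModel, space: ParamSpace,
                          noise: NoiseModel | None = None,
                          n_param: int = 15, n_noise: int = 14,
                          wavelengths=None,
                          rng: np.random.Generator | int = 0
                          ) -> TestSpectraSet:
    """Draw ``n_param`` random valid parameter sets, simulate their spectra
    with the surrogate, and attach ``n_noise`` noisy replicates each
    (the noiseless spectrum is kept alongside)."""
    if n_param < 1 or n_noise < 0:
        raise ValueError("counts must be >= 1 (n_param) and >= 0 (n_noise)")
    from .chromophores import default_fit_wavelengths
    lam = default_fit_wavelengths() if wavelengths is None \
        else np.asarray(wavelengths, float)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    seed = int(rng.integers(2 ** 31))
    rng = np.random.default_rng(seed)

    vecs = space.sample_valid(n_param, rng, lam)
    ops = space.op_matrix_batch(vecs, lam)
    R = surrogate.predict_reflectance(ops.reshape(-1, 8),
                                      warn_out_of_range=False)
    R = R.reshape(n_param, len(lam), -1)
    noisy = np.empty((n_param, n_noise) + R.shape[1:])
    for i in range(n_param):
        for j in range(n_noise):
            noisy[i, j] = R[i] * noise.factors(len(lam), rng)
    return TestSpectraSet(vectors=vecs, truth_ops=ops, noiseless=R,
                          noisy=noisy, wavelengths=lam, seed=seed,
                          noise=noise)


# ---------------------------------------------------------------------------
# error compilation
# ---------------------------------------------------------------------------

@dataclass
class ErrorDistribution:
    """Pooled relative-error samples and empirical confidence intervals."""

    samples: dict                  # OP name -> 1-D array of relative errors
    intervals: dict                # OP name -> {level: (lo, hi)}
    levels: tuple

    def width(self, name: str, level: float) -> float:
        lo, hi = self.intervals[name][level]
        return hi - lo


def relative_op_errors(estimated_ops: np.ndarray,
                       truth_ops: np.ndarray) -> dict:
    """Relative error of each reported OP, averaged over the fitted
    wavelengths: mean((est - truth)/truth)."""
    out = {}
    for name in OP_NAMES:
        col = _OP_COLUMNS[name]
        est = estimated_ops[:, col]
        tru = truth_ops[:, col]
        out[name] = float(np.mean((est - tru) / tru))
    return out


def compile_confidence_intervals(fits, truths, levels=(0.68, 0.95)
                                 ) -> ErrorDistribution:
    """Compile empirical central confidence intervals of the OP errors.

    ``fits`` is a flat list of estimated OP matrices (one per accepted
    solution — multiple solutions enter as separate points) and ``truths``
    the matched ground-truth OP matrices.  The per-wavelength relative
    errors of every fit pool into the histogram as separate samples (a
    wrong scattering exponent then widens the mu_s' band instead of
    averaging away).  Intervals are empirical central quantiles, so a
    level-p interval contains fraction p of the samples by construction.
    """
    if len(fits) != len(truths):
        raise ValueError("every fit needs a matched ground truth")
    if len(fits) < 10:
        logger.warning("only %d samples; intervals will be coarse",
                       len(fits))
    samples = {name: [] for name in OP_NAMES}
    for est, tru in zip(fits, truths):
        for name in OP_NAMES:
            col = _OP_COLUMNS[name]
            rel = (est[:, col] - tru[:, col]) / tru[:, col]
            samples[name].extend(np.atleast_1d(rel))
    samples = {k: np.asarray(v) for k, v in samples.items()}
    intervals = {}
    for name, vals in samples.items():
        intervals[name] = {}
        for p in levels:
            lo, hi = np.quantile(vals, [(1 - p) / 2, (1 + p) / 2])
            intervals[name][p] = (float(lo), float(hi))
    return ErrorDistribution(samples=samples, intervals=intervals,
                             levels=tuple(levels))


# ---------------------------------------------------------------------------
# sensitivity and rank validation
# ---------------------------------------------------------------------------

def sensitivity_analysis(forward, baseline_ops, perturbation: float = 0.1,
                         op_indices=None, bounds=None) -> np.ndarray:
    """Relative reflectance change per relative OP change, by central
    differences around one or more baselines.

    ``forward`` maps (n, 8) OP rows to (n, n_detectors) reflectance;
    ``baseline_ops`` is one 8-vector or a stack; the result is averaged
    over baselines and has shape (n_detectors, len(op_indices)).
    ``bounds`` (lo, hi arrays of length 8) shrinks steps that would leave
    the admissible hull.
    """
    if perturbation == 0:
        raise ValueError("perturbation must be nonzero")
    base = np.atleast_2d(np.asarray(baseline_ops, float))
    idx = list(range(8)) if op_indices is None else list(op_indices)
    R0 = np.asarray(forward(base))
    out = np.zeros((len(base), R0.shape[1], len(idx)))
    for k, j in enumerate(idx):
        for b in range(len(base)):
            step = perturbation
            if bounds is not None:
                lo, hi = bounds
                head = (hi[j] - base[b, j]) / base[b, j]
                foot = (base[b, j] - lo[j]) / base[b, j]
                room = min(head, foot)
                if step > room:
                    logger.warning("perturbation %.3g shrunk to %.3g for "
                                   "OP %d", step, room, j)
                    step = room
            up = base[b].copy()
            dn = base[b].copy()
            up[j] *= (1 + step)
            dn[j] *= (1 - step)
            Ru, Rd = forward(up[None])[0], forward(dn[None])[0]
            out[b, :, k] = (Ru - Rd) / R0[b] / (2 * step)
    return out.mean(axis=0)


def rank_validation(fits_by_target, truths=None) -> dict:
    """Normalized OP error versus spectral-error rank.

    ``fits_by_target`` is a list over targets; each entry is the ordered
    (by fitted spectral error) list of FitResult-like objects exposing
    ``op_spectra``; ``truths`` the matched ground-truth OP matrices.  For
    each target the per-start RMS percent OP error (over wavelengths and
    the six OPs) is min-max normalized to [0, 1]; targets with constant
    error across starts are skipped.  Returns the pooled matrix and
    per-rank medians.
    """
    n_starts = len(fits_by_target[0])
    if any(len(f) != n_starts for f in fits_by_target):
        raise ValueError("every target needs the same number of starts")
    rows = []
    skipped = 0
    for t, fits in enumerate(fits_by_target):
        truth = truths[t]
        errs = []
        for fr in fits:
            est = fr.op_spectra if hasattr(fr, "op_spectra") else fr
            rel = [(est[:, _OP_COLUMNS[n]] - truth[:, _OP_COLUMNS[n]])
                   / truth[:, _OP_COLUMNS[n]] for n in OP_NAMES]
            errs.append(np.sqrt(np.mean(np.square(rel))) * 100.0)
        errs = np.asarray(errs)
        span = errs.max() - errs.min()
        if span <= 1e-12:
            skipped += 1
            logger.info("target %d skipped: constant OP error across "
                        "starts", t)
            continue
        rows.append((errs - errs.min()) / span)
    pooled = np.asarray(rows)
    return {"normalized": pooled,
            "median_by_rank": np.median(pooled, axis=0),
            "n_targets": len(rows), "n_skipped": skipped}
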