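"""Feedforward surrogate of the Monte Carlo forward model.

Maps the eight optical properties (mu_a, mu_s' of scalp, skull, CSF, gray
matter) to diffuse reflectance at the six detectors.  The network is
trained on log-reflectance with z-scored inputs (reflectance spans decades
across source-detector separations) and therefore always predicts strictly
positive reflectance.  Inference is a plain numpy forward pass: vectorized,
fast enough to replace MC inside the iterative inverse loop, and
serialization round-trips bit-exactly.

The full-scale architecture mirrors the production configuration (hidden
widths 850/550/300/150); the default here is a desk-scale (64, 64) network
matched to desk-scale training tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPRegressor

from .chromophores import OPRanges
from .forward import TrainingSet

__all__ = ["SurrogateModel", "train_surrogate", "FULL_SCALE_HIDDEN"]

logger = logging.getLogger(__name__)

FULL_SCALE_HIDDEN = (850, 550, 300, 150)


@dataclass
class SurrogateModel:
    """Weights and normalization of a trained forward surrogate."""

    weights: list                   # per layer, (n_in, n_out)
    biases: list
    x_mean: np.ndarray
    x_std: np.ndarray
    seed: int
    metrics: dict = field(default_factory=dict)
    training_fingerprint: str = ""

    @property
    def n_outputs(self) -> int:
        return self.weights[-1].shape[1]

    def predict_log(self, X) -> np.ndarray:
        """Log-reflectance for rows of eight OPs; vectorized."""
        X = np.atleast_2d(np.asarray(X, float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite optical properties")
        h = (X - self.x_mean) / self.x_std
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def predict_reflectance(self, X, ranges: OPRanges | None = None,
                            warn_out_of_range: bool = True) -> np.ndarray:
        """Reflectance at the detectors for rows of eight OPs
        (mua_scalp, mua_skull, mua_csf, mua_gm, musp x 4, 1/cm).

        Values outside the admissible ranges only trigger a debug-level
        note: the optimizer legitimately probes the constraint boundary.
        """
        X = np.atleast_2d(np.asarray(X, float))
        if warn_out_of_range:
            ranges = ranges or OPRanges.default()
            lo, hi = _range_bounds(ranges)
            if np.any(X < lo - 1e-9) or np.any(X > hi + 1e-9):
                logger.debug("surrogate queried outside admissible OP ranges")
        return np.exp(self.predict_log(X))

    # --- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays = {"x_mean": self.x_mean, "x_std": self.x_std,
                  "seed": np.int64(self.seed),
                  "n_layers": np.int64(len(self.weights)),
                  "fingerprint": self.training_fingerprint}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        for k, v in self.metrics.items():
            arrays[f"metric_{k}"] = np.asarray(v)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with np.load(path, allow_pickle=False) as f:
            n = int(f["n_layers"])
            metrics = {k[len("metric_"):]: f[k]
                       for k in f.files if k.startswith("metric_")}
            return cls(weights=[f[f"W{i}"] for i in range(n)],
                       biases=[f[f"b{i}"] for i in range(n)],
                       x_mean=f["x_mean"], x_std=f["x_std"],
                       seed=int(f["seed"]), metrics=metrics,
                       training_fingerprint=str(f["fingerprint"]))


def _range_bounds(ranges: OPRanges):
    names = ("scalp", "skull", "csf", "gm")
    lo = np.array([ranges.mua[n][0] for n in names]
                  + [ranges.musp[n][0] for n in names])
    hi = np.array([ranges.mua[n][1] for n in names]
                  + [ranges.musp[n][1] for n in names])
    return lo, hi


def _rms_percent(pred_log: np.ndarray, true_log: np.ndarray) -> np.ndarray:
    """Per-output RMS percent error in linear reflectance."""
    ratio = np.exp(pred_log - true_log)
    return np.sqrt(np.mean((ratio - 1.0) ** 2, axis=0)) * 100.0


def train_surrogate(data: TrainingSet, hidden=(64, 64), seed: int = 0,
                    solver: str = "auto", max_epochs: int = 400,
                    patience: int = 20, alpha: float = 1e-6,
                    learning_rate_init: float = 1e-3) -> SurrogateModel:
    """Train the forward surrogate on a TrainingSet.

    Minimizes squared error on log-reflectance.  With the (default) lbfgs
    path, used for desk-scale tables, the optimizer runs to tolerance on
    the train split; with adam, training early-stops on the validation
    split with the given patience and the best-validation weights are
    restored.  Per-detector RMS percent errors on the test split are stored
    in ``metrics``.  A non-finite loss raises with the best state seen.
    """
    Xtr, Ytr = data.subset("train")
    Xv, Yv = data.subset("val")
    Xte, Yte = data.subset("test")
    if len(Xtr) == 0:
        raise ValueError("empty training split")
    xm = Xtr.mean(axis=0)
    xs = Xtr.std(axis=0)
    xs[xs == 0] = 1.0
    ztr = (Xtr - xm) / xs
    ytr = np.log(Ytr)

    if solver == "auto":
        solver = "lbfgs" if len(Xtr) <= 60000 else "adam"

    if solver == "lbfgs":
        mlp = MLPRegressor(hidden_layer_sizes=hidden, solver="lbfgs",
                           alpha=alpha, max_iter=3000, tol=1e-9,
                           random_state=seed)
        mlp.fit(ztr, ytr)
        if not np.isfinite(mlp.loss_):
            raise RuntimeError("surrogate training diverged (NaN loss)")
        weights = [W.copy() for W in mlp.coefs_]
        biases = [b.copy() for b in mlp.intercepts_]
    else:
        mlp = MLPRegressor(hidden_layer_sizes=hidden, solver="adam",
                           alpha=alpha, learning_rate_init=learning_rate_init,
                           max_iter=1, warm_start=True, random_state=seed)
        best = None
        best_val = np.inf
        bad = 0
        import warnings
        for epoch in range(max_epochs):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlp.fit(ztr, ytr)
            if not np.isfinite(mlp.loss_):
                if best is None:
                    raise RuntimeError(
                        "surrogate training diverged (NaN loss) with no "
                        "usable checkpoint")
                logger.warning("divergence at epoch %d; restoring best "
                               "checkpoint", epoch)
                break
            if len(Xv):
                pv = mlp.predict((Xv - xm) / xs)
                val = float(np.mean((pv - np.log(Yv)) ** 2))
            else:
                val = float(mlp.loss_)
            if val < best_val - 1e-12:
                best_val = val
                best = ([W.copy() for W in mlp.coefs_],
                        [b.copy() for b in mlp.intercepts_])
                bad = 0
            else:
                bad += 1
                if bad >= patience:
                    break
        weights, biases = best
    model = SurrogateModel(weights=weights, biases=biases, x_mean=xm,
                           x_std=xs, seed=seed,
                           training_fingerprint=f"seed{data.seed}"
                                                f"-n{data.n_rows}")
    if len(Xte):
        pte = model.predict_log(Xte)
        per_det = _rms_percent(pte, np.log(Yte))
        model.metrics["test_rms_percent"] = per_det
        model.metrics["test_rms_percent_mean"] = np.array(per_det.mean())
    if len(Xv):
        pv = model.predict_log(Xv)
        model.metrics["val_rms_percent"] = _rms_percent(pv, np.log(Yv))
    return model
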