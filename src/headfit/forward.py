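"""Lookup-table forward model: white-MC store, NA conversion, interpolation
and surrogate training data.

One white-MC run is performed per reduced-scattering combination on a
per-compartment grid (the full-scale grid has 13 x 9 x 4 x 6 = 2808 nodes).
Because the runs are white, the reflectance for any absorption combination
follows from the microscopic Beer-Lambert rescaling of the recorded
pathlengths, and reflectance at off-grid scattering values follows from
separable piecewise-polynomial interpolation of log-reflectance across the
four mu_s' axes.  Simulations are run with a wide-open detector acceptance
(NA = 1) for efficiency and converted to the physical fiber NA by a linear
regression on six features (log reflectance, log detected count, mu_a and
mu_s' of scalp and skull).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.linear_model import LinearRegression

from .chromophores import OPRanges
from .head_model import ProbeLayout, VoxelHeadModel
from .mc import WMCResult, mua_dict_to_array, reflectance_from_records, \
    run_white_mc

__all__ = [
    "MuspGrid",
    "LookupTable",
    "NAConversionModel",
    "TrainingSet",
    "wmc_reflectance",
    "build_lookup_table",
    "fit_na_conversion",
    "apply_na_conversion",
    "interpolate_reflectance",
    "generate_training_set",
    "sample_mua_combos",
]

logger = logging.getLogger(__name__)

_AXES = ("scalp", "skull", "csf", "gm")


def wmc_reflectance(result: WMCResult, mua) -> np.ndarray:
    """Microscopic Beer-Lambert reflectance per detector,
    R = sum_i exp(-sum_l mu_a,l PL(i,l)) / N_total."""
    return reflectance_from_records(result, mua)


# ---------------------------------------------------------------------------
# mu_s' grid and lookup table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuspGrid:
    """Sorted reduced-scattering node lists per compartment (1/cm)."""

    scalp: tuple
    skull: tuple
    csf: tuple
    gm: tuple

    def __post_init__(self) -> None:
        for name in _AXES:
            nodes = np.asarray(getattr(self, name), float)
            if len(nodes) < 2 or np.any(np.diff(nodes) <= 0):
                raise ValueError(f"{name} nodes must be strictly increasing "
                                 "with at least two entries")

    @classmethod
    def full_scale(cls) -> "MuspGrid":
        """The production grid: 13 x 9 x 4 x 6 = 2808 combinations."""
        return cls(
            scalp=tuple(np.arange(5.0, 35.1, 2.5)),
            skull=tuple(np.arange(5.0, 35.1, 3.75)),
            csf=(1.0, 1.9, 2.8, 3.7),
            gm=(5.0, 11.0, 17.0, 23.0, 29.0, 35.0),
        )

    @classmethod
    def desk_scale(cls) -> "MuspGrid":
        """A 3 x 3 x 2 x 3 grid spanning the same ranges, for laptop-budget
        simulation studies.  The gray-matter axis needs three nodes: log
        reflectance is markedly convex along it at the long separations,
        and a two-node chord biases interpolated reflectance upward."""
        return cls(scalp=(5.0, 20.0, 35.0), skull=(5.0, 20.0, 35.0),
                   csf=(1.0, 3.7), gm=(5.0, 16.0, 35.0))

    @property
    def shape(self) -> tuple:
        return tuple(len(getattr(self, name)) for name in _AXES)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> list:
        return [np.asarray(getattr(self, name), float) for name in _AXES]

    def combos(self) -> np.ndarray:
        """(size, 4) array of node combinations in C order over
        (scalp, skull, csf, gm)."""
        mesh = np.meshgrid(*self.axes(), indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])

    def combo_dict(self, index: int) -> dict:
        row = self.combos()[index]
        return dict(zip(_AXES, row))

    def contains(self, musp_combo) -> bool:
        q = self._query(musp_combo)
        for val, ax in zip(q, self.axes()):
            if val < ax[0] or val > ax[-1]:
                return False
        return True

    @staticmethod
    def _query(musp_combo) -> np.ndarray:
        if isinstance(musp_combo, dict):
            return np.array([float(musp_combo[a]) for a in _AXES])
        q = np.asarray(musp_combo, float)
        if q.shape[-1] != 4:
            raise ValueError("musp query must have four compartments")
        return q


@dataclass
class LookupTable:
    """White-MC results indexed on the mu_s' grid."""

    grid: MuspGrid
    results: list                  # WMCResult per node, C order
    acceptance_na: float
    base_seed: int
    model_fingerprint: str = ""
    probe_fingerprint: str = ""
    complete: bool = True

    def __post_init__(self) -> None:
        if self.complete and len(self.results) != self.grid.size:
            raise ValueError("entry count does not match grid size")

    @property
    def n_detectors(self) -> int:
        return self.results[0].n_detectors

    @property
    def n_total_per_node(self) -> int:
        return self.results[0].n_total

    def node_reflectance(self, mua) -> np.ndarray:
        """(n_nodes, n_detectors) Beer-Lambert reflectance at every node."""
        mua5 = mua if isinstance(mua, np.ndarray) else mua_dict_to_array(mua)
        return np.stack([reflectance_from_records(r, mua5)
                         for r in self.results])

    def node_detected_counts(self) -> np.ndarray:
        return np.stack([r.n_detected for r in self.results])

    # --- persistence -------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["acceptance_na"] = self.acceptance_na
            f.attrs["base_seed"] = self.base_seed
            f.attrs["complete"] = self.complete
            f.attrs["model_fingerprint"] = self.model_fingerprint
            f.attrs["probe_fingerprint"] = self.probe_fingerprint
            for name in _AXES:
                f.attrs[f"grid_{name}"] = np.asarray(getattr(self.grid, name))
            for i, res in enumerate(self.results):
                grp = f.create_group(f"node{i:05d}")
                grp.create_dataset("det_id", data=res.det_id)
                grp.create_dataset("pathlengths", data=res.pathlengths)
                grp.create_dataset("exit_angle", data=res.exit_angle)
                grp.attrs["n_total"] = res.n_total
                grp.attrs["n_detectors"] = res.n_detectors
                grp.attrs["seed"] = res.seed
                grp.attrs["musp"] = [res.musp_combo[a] for a in _AXES]

    @classmethod
    def load(cls, path) -> "LookupTable":
        with h5py.File(path, "r") as f:
            grid = MuspGrid(**{name: tuple(f.attrs[f"grid_{name}"])
                               for name in _AXES})
            results = []
            for i in range(grid.size):
                grp = f[f"node{i:05d}"]
                musp = dict(zip(_AXES, grp.attrs["musp"]))
                results.append(WMCResult(
                    det_id=grp["det_id"][:],
                    pathlengths=grp["pathlengths"][:],
                    exit_angle=grp["exit_angle"][:],
                    n_total=int(grp.attrs["n_total"]),
                    n_detectors=int(grp.attrs["n_detectors"]),
                    musp_combo=musp, acceptance_na=float(
                        f.attrs["acceptance_na"]),
                    seed=int(grp.attrs["seed"])))
            return cls(grid=grid, results=results,
                       acceptance_na=float(f.attrs["acceptance_na"]),
                       base_seed=int(f.attrs["base_seed"]),
                       model_fingerprint=str(f.attrs["model_fingerprint"]),
                       probe_fingerprint=str(f.attrs["probe_fingerprint"]),
                       complete=bool(f.attrs["complete"]))


def _node_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 2654435761 + 97 + index) % (2 ** 31))


def build_lookup_table(model: VoxelHeadModel, probe: ProbeLayout,
                       grid: MuspGrid, n_photons: int,
                       acceptance_na: float = 1.0, base_seed: int = 0,
                       path_cap_cm: float = 300.0, g: float = 0.9,
                       progress: bool = False) -> LookupTable:
    """Run one white-MC simulation per grid node.

    Per-node seeds derive deterministically from ``base_seed``; rebuilding
    with the same arguments is bit-identical.
    """
    combos = grid.combos()
    results = []
    for i, row in enumerate(combos):
        musp = dict(zip(_AXES, row))
        res = run_white_mc(model, probe, musp, n_photons,
                           acceptance_na=acceptance_na,
                           rng=_node_seed(base_seed, i), g=g,
                           path_cap_cm=path_cap_cm)
        results.append(res)
        if progress:
            logger.info("node %d/%d musp=%s detected=%s",
                        i + 1, len(combos), musp, res.n_detected.tolist())
    return LookupTable(grid=grid, results=results,
                       acceptance_na=acceptance_na, base_seed=base_seed,
                       model_fingerprint=model.fingerprint(),
                       probe_fingerprint=probe.fingerprint())


# ---------------------------------------------------------------------------
# NA conversion
# ---------------------------------------------------------------------------

#: feature order of the NA-conversion regression
NA_FEATURES = ("log_R", "log_N", "mua_scalp", "mua_skull",
               "musp_scalp", "musp_skull")


@dataclass
class NAConversionModel:
    """Linear model for the low-NA / high-NA reflectance ratio."""

    coef: np.ndarray
    intercept: float
    r2: float
    residual_cv: float
    n_obs: int
    seed: int = 0
    target_na: float = 0.12
    clip_events: int = 0

    def predict_ratio(self, features: np.ndarray) -> np.ndarray:
        """Predict the ratio for rows of the six NA_FEATURES; the result is
        clipped into (0, 1] (a fiber cannot collect more than the open
        aperture), counting clip events."""
        X = np.atleast_2d(np.asarray(features, float))
        ratio = X @ self.coef + self.intercept
        n_clip = int(np.sum((ratio <= 0) | (ratio > 1)))
        if n_clip:
            self.clip_events += n_clip
            logger.warning("NA-conversion ratio clipped for %d rows", n_clip)
        return np.clip(ratio, 1e-6, 1.0)


def _pair_design(high: WMCResult, low: WMCResult, mua_samples,
                 musp_combo: dict):
    """Feature rows and ratio targets for one high/low-NA result pair."""
    X, y = [], []
    n_det_high = high.n_detected
    for mua in mua_samples:
        mua5 = mua_dict_to_array(mua) if isinstance(mua, dict) \
            else np.asarray(mua, float)
        r_hi = reflectance_from_records(high, mua5)
        r_lo = reflectance_from_records(low, mua5)
        for d in range(high.n_detectors):
            if r_hi[d] <= 0 or n_det_high[d] == 0:
                continue
            X.append([np.log(r_hi[d]), np.log(n_det_high[d]),
                      mua5[0], mua5[1],
                      musp_combo["scalp"], musp_combo["skull"]])
            y.append(r_lo[d] / r_hi[d])
    return X, y


def fit_na_conversion(paired_runs, seed: int = 0) -> NAConversionModel:
    """Least-squares fit of the low/high-NA reflectance ratio.

    ``paired_runs`` is an iterable of (high_NA_result, low_NA_result,
    mua_samples) where mua_samples is a list of absorption combinations
    spanning the admissible ranges; features are pooled across detectors.
    """
    X, y = [], []
    for high, low, mua_samples in paired_runs:
        Xp, yp = _pair_design(high, low, mua_samples, high.musp_combo)
        X.extend(Xp)
        y.extend(yp)
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(y) < 30:
        raise ValueError(f"need >= 30 paired observations, got {len(y)}")
    # collinearity guard: constant features and perfect pairwise
    # duplicates are dropped (their coefficient is zero); an irreducible
    # rank deficiency is an error
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = sd > 1e-12
    kept_idx = [i for i in range(X.shape[1]) if keep[i]]
    for a_pos in range(len(kept_idx)):
        for b_pos in range(a_pos + 1, len(kept_idx)):
            a, b = kept_idx[a_pos], kept_idx[b_pos]
            if not (keep[a] and keep[b]):
                continue
            c = np.corrcoef(Xc[:, a], Xc[:, b])[0, 1]
            if abs(c) > 1.0 - 1e-9:
                logger.warning("dropping feature %s: duplicate of %s",
                               NA_FEATURES[b], NA_FEATURES[a])
                keep[b] = False
    if keep.sum() == 0:
        model_coef = np.zeros(X.shape[1])
        intercept = float(np.mean(y))
        pred = np.full_like(y, intercept)
        r2 = 0.0
    else:
        Xk = X[:, keep]
        rank = np.linalg.matrix_rank(Xk - Xk.mean(axis=0))
        if rank < keep.sum():
            corr = np.corrcoef(Xc[:, keep], rowvar=False)
            names = [NA_FEATURES[i] for i in range(len(NA_FEATURES))
                     if keep[i]]
            bad = [names[i] for i in range(len(names))
                   if np.any(np.abs(np.delete(corr[i], i)) > 0.999)]
            raise ValueError(
                f"rank-deficient design; collinear features: {bad}")
        model = LinearRegression()
        model.fit(Xk, y)
        pred = model.predict(Xk)
        model_coef = np.zeros(X.shape[1])
        model_coef[keep] = model.coef_
        intercept = float(model.intercept_)
        r2 = float(model.score(Xk, y))
    resid = y - pred
    return NAConversionModel(
        coef=model_coef, intercept=intercept, r2=r2,
        residual_cv=float(np.std(resid) / max(np.mean(y), 1e-12)),
        n_obs=len(y), seed=seed)


def apply_na_conversion(model: NAConversionModel, reflectance,
                        features) -> np.ndarray:
    """Convert wide-aperture reflectance to the physical fiber NA."""
    r = np.asarray(reflectance, float)
    if np.any(r <= 0):
        raise ValueError("reflectance must be positive")
    return r * model.predict_ratio(features)


# ---------------------------------------------------------------------------
# interpolation over the mu_s' grid
# ---------------------------------------------------------------------------

def _axis_weights(nodes: np.ndarray, x: float) -> np.ndarray:
    """Local Lagrange interpolation weights on one axis: cubic where four
    nodes exist, quadratic/linear otherwise.  Exact at the nodes."""
    m = len(nodes)
    if x < nodes[0] - 1e-9 or x > nodes[-1] + 1e-9:
        raise ValueError(f"query {x} outside grid hull "
                         f"[{nodes[0]}, {nodes[-1]}]")
    order = min(4, m)
    j = int(np.searchsorted(nodes, x) - 1)
    j = max(0, min(j, m - 2))
    start = max(0, min(j - (order - 2) // 2, m - order))
    sten = nodes[start:start + order]
    w = np.zeros(m)
    for a in range(order):
        num = 1.0
        for b in range(order):
            if a != b:
                num *= (x - sten[b]) / (sten[a] - sten[b])
        w[start + a] = num
    return w


def _log_with_zero_fill(r_nodes: np.ndarray, fallback: float) -> np.ndarray:
    """log of per-node reflectance where exact zeros (no detected photons)
    are replaced by half the smallest positive reading across nodes for the
    same detector (and absorption sample); a zero reading is evidence of
    "below everything observed", not of any particular magnitude.
    ``r_nodes`` has the node axis first."""
    r = np.asarray(r_nodes, float)
    pos = np.where(r > 0, r, np.inf)
    fill = 0.5 * pos.min(axis=0)
    fill = np.where(np.isfinite(fill), fill, fallback)
    return np.log(np.where(r > 0, r, fill[None]))


def _grid_interp(values: np.ndarray, grid: MuspGrid,
                 queries: np.ndarray) -> np.ndarray:
    """Tensor-product interpolation of ``values`` with leading shape
    ``grid.shape`` at (m, 4) queries; trailing axes pass through.

    Interpolation runs against sqrt(mu_s'): in the diffusive regime log
    reflectance scales with sqrt(mu_a mu_s'_eff), so the sqrt abscissa
    nearly linearizes the node values and sharply reduces the bias of the
    coarse grid (verified by a refinement study against direct runs at
    off-grid scattering values).
    """
    axes = [np.sqrt(ax) for ax in grid.axes()]
    out = []
    for q in np.atleast_2d(queries):
        ws = [_axis_weights(ax, x)
              for ax, x in zip(axes, np.sqrt(np.asarray(q, float)))]
        out.append(np.einsum("abcd...,a,b,c,d->...", values, *ws))
    return np.stack(out)


def interpolate_reflectance(table: LookupTable, musp_combo, mua,
                            floor_counts: float = 0.5) -> np.ndarray:
    """Reflectance at an off-grid mu_s' combination for one absorption
    combination, by separable piecewise-polynomial interpolation of
    log-reflectance across the four mu_s' axes.  Grid-node queries
    reproduce the stored Beer-Lambert value exactly.  Raises outside the
    grid hull (no extrapolation)."""
    q = MuspGrid._query(musp_combo)
    if not table.grid.contains(q):
        raise ValueError("mu_s' query outside the lookup-table hull")
    mua5 = mua if isinstance(mua, np.ndarray) else mua_dict_to_array(mua)
    r_nodes = table.node_reflectance(mua5)
    fallback = floor_counts / table.n_total_per_node
    logr = _log_with_zero_fill(r_nodes, fallback).reshape(
        table.grid.shape + (table.n_detectors,))
    return np.exp(_grid_interp(logr, table.grid, q[None])[0])


# ---------------------------------------------------------------------------
# training-set generation
# ---------------------------------------------------------------------------

def sample_mua_combos(n: int, rng: np.random.Generator,
                      ranges: OPRanges | None = None) -> np.ndarray:
    """(n, 5) absorption samples uniform in the admissible per-compartment
    ranges (scalp, skull, csf, gm), with the WM = GM/2 coupling."""
    ranges = ranges or OPRanges.default()
    cols = []
    for name in _AXES:
        lo, hi = ranges.mua[name]
        cols.append(rng.uniform(lo, hi, n))
    mua = np.column_stack(cols)
    return np.column_stack([mua, mua[:, 3] / 2.0])


@dataclass
class TrainingSet:
    """OP -> reflectance rows with a train/validation/test split."""

    X: np.ndarray                  # (n, 8) mua then musp of the 4 compartments
    Y: np.ndarray                  # (n, n_detectors) reflectance
    split: np.ndarray              # (n,) 0 train / 1 val / 2 test
    seed: int
    acceptance_na: float
    fractions: tuple = (0.75, 0.10, 0.15)

    def subset(self, which: str):
        code = {"train": 0, "val": 1, "test": 2}[which]
        m = self.split == code
        return self.X[m], self.Y[m]

    @property
    def n_rows(self) -> int:
        return len(self.X)


def _split_labels(n: int, fractions, rng: np.random.Generator) -> np.ndarray:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    lab = np.full(n, 2, np.int8)
    perm = rng.permutation(n)
    lab[perm[:n_train]] = 0
    lab[perm[n_train:n_train + n_val]] = 1
    return lab


def training_row_count(n_nodes: int, n_musp_extra: int, n_mua: int) -> int:
    """Bookkeeping for the generator: (grid nodes + interpolated mu_s'
    combinations) x absorption combinations."""
    return (n_nodes + n_musp_extra) * n_mua


def generate_training_set(table: LookupTable, n_mua: int = 3000,
                          n_musp_extra: int = 3000,
                          na_model: NAConversionModel | None = None,
                          ranges: OPRanges | None = None,
                          rng: np.random.Generator | int = 0,
                          floor_counts: float = 0.5,
                          mua_block: int = 256) -> TrainingSet:
    """Expand the lookup table into surrogate training rows.

    Rows are (grid nodes + ``n_musp_extra`` random in-hull mu_s' combos)
    x ``n_mua`` random absorption combos; reflectance is NA-converted when
    ``na_model`` is given; rows with a zero-count detector reading are
    dropped.  Deterministic given the rng seed.
    """
    if n_mua < 1 or n_musp_extra < 0:
        raise ValueError("n_mua must be >= 1 and n_musp_extra >= 0")
    if not table.complete:
        raise ValueError("lookup table is incomplete")
    ranges = ranges or OPRanges.default()
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    seed_val = int(rng.integers(2 ** 31))
    rng = np.random.default_rng(seed_val)

    mua_samples = sample_mua_combos(n_mua, rng, ranges)   # (n_mua, 5)
    node_combos = table.grid.combos()                     # (n_nodes, 4)
    axes = table.grid.axes()
    extra = np.column_stack([rng.uniform(ax[0], ax[-1], n_musp_extra)
                             for ax in axes])             # (n_extra, 4)

    nd = table.n_detectors
    n_nodes = table.grid.size
    floor = floor_counts / table.n_total_per_node
    logn = np.log(np.maximum(table.node_detected_counts(), 1.0))

    # per-node reflectance for every mua block: (n_nodes, n_mua, nd)
    r_nodes = np.empty((n_nodes, n_mua, nd))
    for i, res in enumerate(table.results):
        pl = res.pathlengths
        det = res.det_id
        for j0 in range(0, n_mua, mua_block):
            blk = mua_samples[j0:j0 + mua_block]
            w = np.exp(-(pl @ blk.T))                    # (k, b)
            acc = np.zeros((nd, w.shape[1]))
            np.add.at(acc, det, w)
            r_nodes[i, j0:j0 + mua_block] = acc.T / res.n_total

    # zero readings (no detected photons at that node) are filled with half
    # the smallest positive reading of the same detector and absorption
    # sample, so rows stay strictly positive without overriding real data
    log_nodes = _log_with_zero_fill(r_nodes, floor)

    # interpolate the extra mu_s' combos across the grid
    grid_shape = table.grid.shape
    vals = log_nodes.reshape(grid_shape + (n_mua, nd))
    if n_musp_extra:
        log_extra = _grid_interp(vals, table.grid, extra)  # (n_extra,n_mua,nd)
    else:
        log_extra = np.empty((0, n_mua, nd))

    def rows_from(log_r, musp_rows):
        n_m = len(musp_rows)
        Y = np.exp(log_r.reshape(n_m * n_mua, nd))
        mu_rep = np.repeat(musp_rows, n_mua, axis=0)
        mua_rep = np.tile(mua_samples[:, :4], (n_m, 1))
        X = np.column_stack([mua_rep, mu_rep])
        return X, Y, mu_rep, mua_rep

    Xn, Yn, mu_n, mua_n = rows_from(log_nodes, node_combos)
    Xe, Ye, mu_e, mua_e = rows_from(log_extra, extra)
    X = np.vstack([Xn, Xe])
    Y = np.vstack([Yn, Ye])
    mu_all = np.vstack([mu_n, mu_e])
    mua_all = np.vstack([mua_n, mua_e])

    if na_model is not None:
        # detected-count feature, interpolated across the grid for the
        # extra mu_s' combinations
        logn_grid = logn.reshape(grid_shape + (nd,))
        logn_rows = [np.repeat(logn, n_mua, axis=0)]
        if n_musp_extra:
            logn_rows.append(np.repeat(
                _grid_interp(logn_grid, table.grid, extra), n_mua, axis=0))
        logn_rows = np.vstack(logn_rows)
        for d in range(nd):
            feats = np.column_stack([
                np.log(Y[:, d]), logn_rows[:, d],
                mua_all[:, 0], mua_all[:, 1], mu_all[:, 0], mu_all[:, 1]])
            Y[:, d] = apply_na_conversion(na_model, Y[:, d], feats)

    split = _split_labels(len(X), (0.75, 0.10, 0.15), rng)
    return TrainingSet(X=X, Y=Y, split=split, seed=seed_val,
                       acceptance_na=(table.acceptance_na if na_model is None
                                      else na_model.target_na))
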