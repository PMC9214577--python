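"""Synthetic voxel head models and scalp probe placement.

A head model is a 3-D integer label volume with codes

    0 outer medium, 1 scalp, 2 skull, 3 CSF, 4 gray matter,
    5 white matter, 6 sinus (air pocket)

on an isotropic voxel grid (default edge 0.93 mm).  The generator builds
either a flat layered slab or a spherically curved four-shell geometry with
optional smooth interface undulation and an ellipsoidal frontal-sinus
pocket, standing in for an MRI-segmented head.  A reader for externally
segmented label volumes (NIfTI + JSON sidecar) is provided; segmentation
itself is out of scope.

Axis convention: array axes are (x, y, z) with z the depth axis; the scalp
surface of a flat slab is the z = 0 plane and positions are measured in cm
at voxel centers (voxel (i,j,k) center = ((i+.5)e, (j+.5)e, (k+.5)e) with e
the edge in cm).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .chromophores import LABELS

__all__ = [
    "VoxelHeadModel",
    "Detector",
    "ProbeLayout",
    "build_synthetic_head",
    "place_probe",
    "ring_probe",
    "check_column_ordering",
]

_LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: anatomical order required along an interior column (sinus may interleave)
_ORDER = (LABELS["scalp"], LABELS["skull"], LABELS["csf"],
          LABELS["gm"], LABELS["wm"])


@dataclass
class VoxelHeadModel:
    """Labeled voxel volume plus grid metadata."""

    labels: np.ndarray              # int8, shape (nx, ny, nz)
    voxel_edge_mm: float = 0.93
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.voxel_edge_mm <= 0:
            raise ValueError("voxel edge must be positive")
        bad = set(np.unique(self.labels)) - set(LABELS.values())
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    @property
    def edge_cm(self) -> float:
        return self.voxel_edge_mm / 10.0

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def extent_cm(self) -> np.ndarray:
        return np.array(self.labels.shape) * self.edge_cm

    def label_histogram(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {_LABEL_NAMES[int(v)]: int(c) for v, c in zip(vals, counts)}

    def fingerprint(self) -> str:
        h = hashlib.sha1(self.labels.tobytes())
        h.update(np.float64(self.voxel_edge_mm).tobytes())
        return h.hexdigest()[:16]

    def boundary_distance_map(self) -> np.ndarray:
        """Per-voxel distance (voxel units, center-to-center) to the nearest
        voxel of a different label or to the grid edge.  Used by the photon
        transport kernel to take free-flight steps away from label
        boundaries; computed once and cached."""
        cached = getattr(self, "_bdist", None)
        if cached is not None:
            return cached
        from scipy import ndimage
        out = np.zeros(self.labels.shape, np.float32)
        for lab in np.unique(self.labels):
            mask = np.pad(self.labels == lab, 1, constant_values=False)
            d = ndimage.distance_transform_edt(mask)[1:-1, 1:-1, 1:-1]
            sel = self.labels == lab
            out[sel] = d[sel]
        object.__setattr__(self, "_bdist", out)
        return out

    def surface_z_index(self, ix: int, iy: int) -> int:
        """Index of the first tissue voxel along +z in column (ix, iy)."""
        col = self.labels[ix, iy, :]
        nz = np.nonzero(col != LABELS["outer"])[0]
        if len(nz) == 0:
            raise ValueError(f"column ({ix},{iy}) is entirely outer medium")
        return int(nz[0])

    def depth_profile_mm(self, ix: int, iy: int) -> dict:
        """Depth (mm, from the surface) of the first occurrence of each
        tissue label in a column."""
        top = self.surface_z_index(ix, iy)
        col = self.labels[ix, iy, top:]
        out = {}
        for code in np.unique(col):
            name = _LABEL_NAMES[int(code)]
            out[name] = float(np.nonzero(col == code)[0][0]
                              * self.voxel_edge_mm)
        return out

    # --- I/O ---------------------------------------------------------------

    def save(self, path) -> None:
        """Write a NIfTI label volume plus a JSON sidecar."""
        path = Path(path)
        affine = np.diag([self.voxel_edge_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), path)
        sidecar = {
            "voxel_edge_mm": self.voxel_edge_mm,
            "origin_mm": list(map(float, self.origin_mm)),
            "label_map": {k: v for k, v in LABELS.items()},
            "provenance": self.provenance,
        }
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelHeadModel":
        path = Path(path)
        img = nib.load(path)
        side = path.with_suffix("").with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        edge = meta.get("voxel_edge_mm", float(img.header.get_zooms()[0]))
        return cls(labels=np.asanyarray(img.dataobj).astype(np.int8),
                   voxel_edge_mm=edge,
                   origin_mm=np.asarray(meta.get("origin_mm", [0, 0, 0]),
                                        float),
                   provenance=meta.get("provenance", {}))


@dataclass(frozen=True)
class Detector:
    """One detector site on the scalp surface.

    mode "disc": circular fiber face of radius ``r1_cm`` at ``position_cm``.
    mode "ring": annulus r0..r1 (cm) around the source on a flat surface —
    an azimuthal average that boosts photon statistics on symmetric models.
    """

    position_cm: np.ndarray
    normal_out: np.ndarray          # outward unit normal
    sds_cm: float
    mode: str = "disc"
    r0_cm: float = 0.0
    r1_cm: float = 0.02             # 0.4 mm core diameter

    def area_cm2(self) -> float:
        if self.mode == "ring":
            return float(np.pi * (self.r1_cm ** 2 - self.r0_cm ** 2))
        return float(np.pi * self.r1_cm ** 2)


@dataclass(frozen=True)
class ProbeLayout:
    """Source fiber bundle plus the multidistance detector set."""

    source_pos_cm: np.ndarray
    source_normal_in: np.ndarray    # unit normal pointing into tissue
    detectors: tuple                # Detector, ordered by increasing SDS
    source_radius_cm: float = 0.21  # active bundle radius 2.1 mm
    source_na: float = 0.39
    acceptance_na: float = 0.12
    fiber_n: float = 1.457

    def sds_list(self) -> np.ndarray:
        return np.array([d.sds_cm for d in self.detectors])

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.asarray(self.source_pos_cm, float).tobytes())
        for d in self.detectors:
            h.update(np.asarray(d.position_cm, float).tobytes())
            h.update(np.float64([d.r0_cm, d.r1_cm, d.sds_cm]).tobytes())
            h.update(d.mode.encode())
        return h.hexdigest()[:16]


#: the six source-detector separations of the probe, in cm
DEFAULT_SDS_CM = (0.8, 1.5, 2.12, 3.0, 3.35, 4.5)


def _smooth_field(nx: int, ny: int, edge_mm: float, amplitude_mm: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean random undulation (mm) over the (x, y) plane built
    from a handful of low-frequency cosines."""
    if amplitude_mm <= 0:
        return np.zeros((nx, ny))
    x = np.arange(nx)[:, None] * edge_mm
    y = np.arange(ny)[None, :] * edge_mm
    f = np.zeros((nx, ny))
    for _ in range(6):
        kx, ky = rng.uniform(-0.05, 0.05, 2)  # cycles/mm, >=20 mm period
        phase = rng.uniform(0, 2 * np.pi)
        f += np.cos(2 * np.pi * (kx * x + ky * y) + phase)
    f *= amplitude_mm / max(np.abs(f).max(), 1e-12)
    return f


def build_synthetic_head(
    layer_thicknesses_mm=(5.0, 7.0, 2.0, 4.0),
    curvature_radius_mm: float | None = None,
    sinus: dict | None = None,
    dims=(120, 80, 64),
    voxel_edge_mm: float = 0.93,
    undulation_mm: float = 0.0,
    seed: int = 0,
) -> VoxelHeadModel:
    """Generate a synthetic layered head model.

    ``layer_thicknesses_mm`` gives scalp, skull, CSF and GM thickness; the
    remainder is white matter.  ``curvature_radius_mm=None`` produces a flat
    slab with the scalp surface at z=0; a finite radius produces a spherical
    four-shell geometry whose crown touches z=0 at the lateral center.
    ``sinus`` is an optional dict with ``center_mm`` and ``semiaxes_mm``
    carving an air pocket out of the skull.  Deterministic given ``seed``.
    """
    t = np.asarray(layer_thicknesses_mm, float)
    if len(t) != 4 or np.any(t <= 0):
        raise ValueError("need four positive layer thicknesses "
                         "(scalp, skull, CSF, GM)")
    nx, ny, nz = map(int, dims)
    e = float(voxel_edge_mm)
    rng = np.random.default_rng(seed)
    # depth of voxel centers below the nominal surface, per column
    iz = (np.arange(nz) + 0.5) * e
    interfaces = np.cumsum(t)  # scalp/skull, skull/CSF, CSF/GM, GM/WM
    und = [_smooth_field(nx, ny, e, undulation_mm, rng) for _ in interfaces]

    if curvature_radius_mm is None:
        depth = np.broadcast_to(iz, (nx, ny, nz))
    else:
        R = float(curvature_radius_mm)
        cx = (nx * e) / 2.0
        cy = (ny * e) / 2.0
        x = (np.arange(nx)[:, None, None] + 0.5) * e
        y = (np.arange(ny)[None, :, None] + 0.5) * e
        z = iz[None, None, :]
        # distance from the sphere center at (cx, cy, R); depth = R - r
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - R) ** 2)
        depth = R - r

    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    labels[depth > 0] = LABELS["wm"]
    order = (LABELS["scalp"], LABELS["skull"], LABELS["csf"], LABELS["gm"])
    lower, u_prev = 0.0, 0.0  # surface itself is not undulated
    for code, upper, u in zip(order, interfaces, und):
        d_lo = lower + u_prev
        d_hi = upper + u[..., None]
        labels[(depth > d_lo) & (depth <= d_hi)] = code
        lower, u_prev = upper, u[..., None]
    # enforce ordering where undulation squeezed a layer away: nothing to do,
    # masks are disjoint by construction (d_lo < d_hi guaranteed below)
    if undulation_mm >= min(t) / 2:
        raise ValueError("undulation amplitude must be below half the "
                         "thinnest layer")

    if sinus is not None:
        c = np.asarray(sinus["center_mm"], float)
        a = np.asarray(sinus["semiaxes_mm"], float)
        x = (np.arange(nx)[:, None, None] + 0.5) * e
        y = (np.arange(ny)[None, :, None] + 0.5) * e
        z = (np.arange(nz)[None, None, :] + 0.5) * e
        inside = (((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2
                  + ((z - c[2]) / a[2]) ** 2) <= 1.0
        mask = inside & (labels == LABELS["skull"])
        labels[mask] = LABELS["sinus"]

    model = VoxelHeadModel(
        labels=labels, voxel_edge_mm=e,
        provenance={"generator": "build_synthetic_head",
                    "layer_thicknesses_mm": list(map(float, t)),
                    "curvature_radius_mm": curvature_radius_mm,
                    "undulation_mm": undulation_mm,
                    "sinus": sinus, "seed": seed})
    model.provenance["label_histogram"] = model.label_histogram()
    return model


def check_column_ordering(model: VoxelHeadModel, n_columns: int = 100,
                          seed: int = 0) -> bool:
    """Scan random interior columns and verify the anatomical label order
    scalp -> skull -> CSF -> GM -> WM (sinus pockets allowed inside the
    skull span).  Raises on violation, returns True otherwise."""
    rng = np.random.default_rng(seed)
    nx, ny, _ = model.shape
    checked = 0
    for _ in range(n_columns * 5):
        if checked >= n_columns:
            break
        ix = int(rng.integers(0, nx))
        iy = int(rng.integers(0, ny))
        col = model.labels[ix, iy, :]
        tissue = col[(col != LABELS["outer"]) & (col != LABELS["sinus"])]
        if len(tissue) == 0:
            continue
        seq = [int(c) for c, _ in _runs(tissue)]
        expected = [c for c in _ORDER if c in seq]
        if seq != expected:
            raise AssertionError(
                f"column ({ix},{iy}) violates anatomical order: {seq}")
        checked += 1
    return True


def _runs(arr):
    out = []
    for v in arr:
        if not out or out[-1][0] != v:
            out.append([int(v), 1])
        else:
            out[-1][1] += 1
    return out


# ---------------------------------------------------------------------------
# probe placement
# ---------------------------------------------------------------------------

def _surface_point_flat(model, anchor_cm):
    return np.array([anchor_cm[0], anchor_cm[1], 0.0])


def place_probe(model: VoxelHeadModel, sds_list_cm=DEFAULT_SDS_CM,
                anchor_cm=None, source_radius_cm: float = 0.21,
                source_na: float = 0.39, acceptance_na: float = 0.12,
                detector_radius_cm: float = 0.02) -> ProbeLayout:
    """Place the source at ``anchor_cm`` on the scalp surface and the
    detectors along a surface geodesic at the requested separations.

    On a flat slab the geodesic is the +x line through the anchor; on a
    spherically curved model it is the great circle through the crown, with
    arc length equal to the requested SDS.  Raises if a separation is
    unreachable within the model extent.
    """
    sds = np.asarray(sds_list_cm, float)
    ext = model.extent_cm()
    curved = model.provenance.get("curvature_radius_mm") is not None

    if anchor_cm is None:
        if curved:
            anchor_cm = (ext[0] / 2.0, ext[1] / 2.0)
        else:
            anchor_cm = (ext[0] * 0.25, ext[1] / 2.0)
    ax, ay = float(anchor_cm[0]), float(anchor_cm[1])

    margin = 0.3  # cm of lateral clearance kept around every detector
    if not curved:
        src = np.array([ax, ay, 0.0])
        max_sds = ext[0] - ax - margin
        if np.any(sds > max_sds):
            raise ValueError(f"SDS {sds.max():.2f} cm unreachable; max "
                             f"feasible is {max_sds:.2f} cm")
        dets = []
        for s in sds:
            dets.append(Detector(
                position_cm=np.array([ax + s, ay, 0.0]),
                normal_out=np.array([0.0, 0.0, -1.0]), sds_cm=float(s),
                mode="disc", r1_cm=detector_radius_cm))
        normal_in = np.array([0.0, 0.0, 1.0])
    else:
        R = model.provenance["curvature_radius_mm"] / 10.0  # cm
        center = np.array([ext[0] / 2.0, ext[1] / 2.0, R])
        src = np.array([ext[0] / 2.0, ext[1] / 2.0, 0.0])
        max_phi = np.pi / 2 * 0.8
        if np.any(sds / R > max_phi):
            raise ValueError(f"SDS {sds.max():.2f} cm unreachable on sphere; "
                             f"max feasible is {R * max_phi:.2f} cm arc")
        dets = []
        for s in sds:
            phi = s / R  # arc length -> polar angle from crown
            pos = center + R * np.array([np.sin(phi), 0.0, -np.cos(phi)])
            if pos[0] > ext[0] - margin:
                raise ValueError(f"SDS {s:.2f} cm leaves the model extent")
            n_out = (pos - center) / R
            dets.append(Detector(position_cm=pos, normal_out=n_out,
                                 sds_cm=float(s), mode="disc",
                                 r1_cm=detector_radius_cm))
        normal_in = np.array([0.0, 0.0, 1.0])

    return ProbeLayout(source_pos_cm=src, source_normal_in=normal_in,
                       detectors=tuple(dets), source_radius_cm=source_radius_cm,
                       source_na=source_na, acceptance_na=acceptance_na)


def ring_probe(model: VoxelHeadModel, sds_list_cm=DEFAULT_SDS_CM,
               ring_halfwidth_cm=0.1, anchor_cm=None,
               source_radius_cm: float = 0.0, source_na: float = 0.0,
               acceptance_na: float = 1.0) -> ProbeLayout:
    """Annular detectors around the source on a flat model — azimuthally
    averaged collection for desk-scale photon budgets.  The default pencil
    source keeps the geometry exactly radially symmetric.
    ``ring_halfwidth_cm`` may be a scalar or one value per separation
    (wider far rings trade radial resolution for photon statistics)."""
    if model.provenance.get("curvature_radius_mm") is not None:
        raise ValueError("ring detectors require a flat model")
    sds = np.asarray(sds_list_cm, float)
    hw = np.broadcast_to(np.asarray(ring_halfwidth_cm, float),
                         sds.shape).copy()
    ext = model.extent_cm()
    if anchor_cm is None:
        anchor_cm = (ext[0] / 2.0, ext[1] / 2.0)
    ax, ay = float(anchor_cm[0]), float(anchor_cm[1])
    max_sds = min(ax, ay, ext[0] - ax, ext[1] - ay) - hw.max() - 0.2
    if np.any(sds > max_sds):
        raise ValueError(f"SDS {sds.max():.2f} cm unreachable; max feasible "
                         f"is {max_sds:.2f} cm")
    # rings may overlap: each detector tallies exiting photons
    # independently
    src = np.array([ax, ay, 0.0])
    dets = []
    for s, h in zip(sds, hw):
        dets.append(Detector(
            position_cm=src.copy(), normal_out=np.array([0.0, 0.0, -1.0]),
            sds_cm=float(s), mode="ring",
            r0_cm=max(s - h, 0.0), r1_cm=s + h))
    return ProbeLayout(source_pos_cm=src,
                       source_normal_in=np.array([0.0, 0.0, 1.0]),
                       detectors=tuple(dets),
                       source_radius_cm=source_radius_cm,
                       source_na=source_na, acceptance_na=acceptance_na)
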