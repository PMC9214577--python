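"""Voxel-based Monte Carlo photon transport.

Photons are launched from a fiber-bundle source into the labeled voxel
volume, propagated with free paths drawn from the local scattering
coefficient mu_s = mu_s'/(1-g), deflected by Henyey-Greenstein sampling at
a fixed anisotropy, and transported ray-exactly through the voxel grid so
that per-compartment pathlengths are exact per segment.  Refractive-index
mismatches occur only at the outer boundary (tissue 1.4 <-> outer medium /
fiber 1.457) and at sinus air pockets (1.4 <-> 1.0); interior tissue
boundaries are index-matched.

The engine is "white": absorption is never applied during transport.
Each detected photon carries its pathlengths PL(i,l) in the five tissue
compartments, so the reflectance for any absorption combination follows
from the microscopic Beer-Lambert law

    R = ( sum_i exp(-sum_l mu_a,l PL(i,l)) ) / N_total .

A direct absorbing-mode wrapper applies exactly this continuous attenuation
along the recorded paths, making the white-MC rescaling and the absorbing
oracle agree by construction at equal seed and statistically at different
seeds.

All lengths are in cm, coefficients in 1/cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .chromophores import COMPARTMENTS, LABELS, OPRanges
from .head_model import ProbeLayout, VoxelHeadModel

__all__ = [
    "RngConfig",
    "WMCResult",
    "run_white_mc",
    "run_absorbing_mc",
    "reflectance_from_records",
    "mean_partial_pathlength",
    "mua_dict_to_array",
    "musp_dict_to_labels",
]

# --------------------------------------------------------------------------
# counter-based RNG (splitmix64): per-photon streams independent of
# scheduling order
# --------------------------------------------------------------------------

_U1 = np.uint64(0x9E3779B97F4A7C15)
_U2 = np.uint64(0xBF58476D1CE4E5B9)
_U3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.1102230246251565e-16  # 2**-53


@njit(cache=True, inline="always")
def _rand(state):
    state[0] = state[0] + _U1
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _U2
    z = (z ^ (z >> np.uint64(27))) * _U3
    z = z ^ (z >> np.uint64(31))
    return float(z >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _fresnel_unpolarized(n1, n2, ci):
    """Unpolarized Fresnel reflectance for incidence cosine ci (>0)."""
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if g < 1e-6:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _scatter_dir(dx, dy, dz, g, state):
    """Henyey-Greenstein deflection; azimuth sampled trig-free."""
    cth = _hg_cos(g, _rand(state))
    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
    while True:
        a = 2.0 * _rand(state) - 1.0
        b = 2.0 * _rand(state) - 1.0
        s2 = a * a + b * b
        if s2 > 1e-12 and s2 <= 1.0:
            break
    inv = 1.0 / s2
    cph = (a * a - b * b) * inv
    sph = 2.0 * a * b * inv
    if dz > 0.99999 or dz < -0.99999:
        ux = sth * cph
        uy = sth * sph
        uz = cth if dz > 0 else -cth
    else:
        den = math.sqrt(1.0 - dz * dz)
        ux = sth * (dx * dz * cph - dy * sph) / den + dx * cth
        uy = sth * (dy * dz * cph + dx * sph) / den + dy * cth
        uz = -sth * cph * den + dz * cth
    nrm = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
    return ux * nrm, uy * nrm, uz * nrm


@njit(cache=True)
def _kernel(labels, bdist, edge, mus7, g7, n7,
            src_pos, src_norm, src_t1, src_t2, src_radius, src_na, n_fiber,
            det_mode, det_pos, det_norm, det_r0, det_r1, cos_amax, accept_all,
            n_photons, seed, path_cap,
            out_det, out_pl, out_ang, counts):
    nx, ny, nz = labels.shape
    inv_edge = 1.0 / edge
    state = np.empty(1, dtype=np.uint64)
    pl = np.empty(5, dtype=np.float64)
    nd = det_mode.shape[0]
    n_store = 0
    # launch cone half-angle inside the fiber
    sa = src_na / n_fiber
    if sa > 1.0:
        sa = 1.0
    cos_src_max = math.sqrt(1.0 - sa * sa)

    for ip in range(n_photons):
        state[0] = (np.uint64(seed) + np.uint64(1)) * _U2 \
            + np.uint64(ip + 1) * _U3
        _rand(state)
        _rand(state)

        # ---- launch: position on the source disc, direction in the cone
        if src_radius > 0.0:
            rr = src_radius * math.sqrt(_rand(state))
            th = 2.0 * math.pi * _rand(state)
            ox = rr * math.cos(th)
            oy = rr * math.sin(th)
        else:
            ox = 0.0
            oy = 0.0
        px = src_pos[0] + ox * src_t1[0] + oy * src_t2[0]
        py = src_pos[1] + ox * src_t1[1] + oy * src_t2[1]
        pz = src_pos[2] + ox * src_t1[2] + oy * src_t2[2]
        if src_na > 0.0:
            cb = cos_src_max + (1.0 - cos_src_max) * _rand(state)
            sb = math.sqrt(max(0.0, 1.0 - cb * cb))
            ph = 2.0 * math.pi * _rand(state)
            dx = sb * math.cos(ph) * src_t1[0] + sb * math.sin(ph) * src_t2[0] \
                + cb * src_norm[0]
            dy = sb * math.cos(ph) * src_t1[1] + sb * math.sin(ph) * src_t2[1] \
                + cb * src_norm[1]
            dz = sb * math.cos(ph) * src_t1[2] + sb * math.sin(ph) * src_t2[2] \
                + cb * src_norm[2]
        else:
            dx, dy, dz = src_norm[0], src_norm[1], src_norm[2]
            cb = 1.0

        # ---- entry Fresnel (fiber n -> tissue n at normal = src_norm)
        n_tissue = n7[1]
        rf = _fresnel_unpolarized(n_fiber, n_tissue, cb)
        if _rand(state) < rf:
            counts[3] += 1  # specular reflection at launch
            continue
        # refract: scale tangential part, keep normal sign
        eta = n_fiber / n_tissue
        st2 = eta * eta * (1.0 - cb * cb)
        ct = math.sqrt(max(0.0, 1.0 - st2))
        tx = dx - cb * src_norm[0]
        ty = dy - cb * src_norm[1]
        tz = dz - cb * src_norm[2]
        dx = eta * tx + ct * src_norm[0]
        dy = eta * ty + ct * src_norm[1]
        dz = eta * tz + ct * src_norm[2]
        nrm = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= nrm
        dy /= nrm
        dz /= nrm

        # ---- locate entry voxel (skip any outer-medium voxels under the
        # launch point; photon enters the first tissue voxel)
        eps = 1e-9
        px += dx * eps
        py += dy * eps
        pz += dz * eps
        ix = int(math.floor(px / edge))
        iy = int(math.floor(py / edge))
        iz = int(math.floor(pz / edge))
        ok = True
        guard = 0
        while True:
            if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                ok = False
                break
            lab = labels[ix, iy, iz]
            if lab != 0:
                break
            # advance through outer voxels to the next face
            tmin = 1e30
            axis = 0
            if dx > 1e-12:
                t = ((ix + 1) * edge - px) / dx
                if t < tmin:
                    tmin = t
                    axis = 0
            elif dx < -1e-12:
                t = (ix * edge - px) / dx
                if t < tmin:
                    tmin = t
                    axis = 0
            if dy > 1e-12:
                t = ((iy + 1) * edge - py) / dy
                if t < tmin:
                    tmin = t
                    axis = 1
            elif dy < -1e-12:
                t = (iy * edge - py) / dy
                if t < tmin:
                    tmin = t
                    axis = 1
            if dz > 1e-12:
                t = ((iz + 1) * edge - pz) / dz
                if t < tmin:
                    tmin = t
                    axis = 2
            elif dz < -1e-12:
                t = (iz * edge - pz) / dz
                if t < tmin:
                    tmin = t
                    axis = 2
            if tmin < 0.0:
                tmin = 0.0
            px += dx * tmin
            py += dy * tmin
            pz += dz * tmin
            if axis == 0:
                ix += 1 if dx > 0 else -1
                px = (ix + (0 if dx > 0 else 1)) * edge
            elif axis == 1:
                iy += 1 if dy > 0 else -1
                py = (iy + (0 if dy > 0 else 1)) * edge
            else:
                iz += 1 if dz > 0 else -1
                pz = (iz + (0 if dz > 0 else 1)) * edge
            guard += 1
            if guard > nx + ny + nz:
                ok = False
                break
        if not ok:
            counts[1] += 1  # left the volume without entering tissue
            continue

        for k in range(5):
            pl[k] = 0.0
        total = 0.0
        tau = -math.log(1.0 - _rand(state))
        safe = 0.0
        have_idx = True
        fate = 1  # 1 escaped, 2 capped

        while True:
            if safe > 0.0:
                # free flight: guaranteed inside a single-label region, no
                # face bookkeeping needed
                mus = mus7[lab]
                if mus > 0.0:
                    s = tau / mus
                    if s <= safe:
                        px += dx * s
                        py += dy * s
                        pz += dz * s
                        if lab <= 5:
                            pl[lab - 1] += s
                        total += s
                        safe -= s
                        if total > path_cap:
                            fate = 2
                            break
                        dx, dy, dz = _scatter_dir(dx, dy, dz, g7[lab], state)
                        tau = -math.log(1.0 - _rand(state))
                        continue
                px += dx * safe
                py += dy * safe
                pz += dz * safe
                if lab <= 5:
                    pl[lab - 1] += safe
                total += safe
                if mus > 0.0:
                    tau -= mus * safe
                safe = 0.0
                have_idx = False
                if total > path_cap:
                    fate = 2
                    break
                continue

            if not have_idx:
                ix = int(math.floor((px + dx * 1e-9) * inv_edge))
                iy = int(math.floor((py + dy * 1e-9) * inv_edge))
                iz = int(math.floor((pz + dz * 1e-9) * inv_edge))
                if (ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny
                        or iz >= nz):
                    break  # numerical corner case: count as escaped
                lab = labels[ix, iy, iz]
                if lab == 0:
                    break
                have_idx = True

            dvox = bdist[ix, iy, iz]
            if dvox >= 1.6:
                # the nearest different-label voxel face is >= (dvox - 0.5)
                # voxel units from this voxel center; the photon is within
                # sqrt(3)/2 ~ 0.87 units of that center
                safe = (dvox - 1.45) * edge
                continue

            # near a label boundary: ray-exact single voxel-face step
            mus = mus7[lab]
            # distance to the next voxel face
            tmin = 1e30
            axis = 0
            if dx > 1e-12:
                t = ((ix + 1) * edge - px) / dx
                if t < tmin:
                    tmin = t
                    axis = 0
            elif dx < -1e-12:
                t = (ix * edge - px) / dx
                if t < tmin:
                    tmin = t
                    axis = 0
            if dy > 1e-12:
                t = ((iy + 1) * edge - py) / dy
                if t < tmin:
                    tmin = t
                    axis = 1
            elif dy < -1e-12:
                t = (iy * edge - py) / dy
                if t < tmin:
                    tmin = t
                    axis = 1
            if dz > 1e-12:
                t = ((iz + 1) * edge - pz) / dz
                if t < tmin:
                    tmin = t
                    axis = 2
            elif dz < -1e-12:
                t = (iz * edge - pz) / dz
                if t < tmin:
                    tmin = t
                    axis = 2
            if tmin < 0.0:
                tmin = 0.0

            if mus > 0.0:
                s_scat = tau / mus
                if s_scat <= tmin:
                    # scatter inside this voxel
                    px += dx * s_scat
                    py += dy * s_scat
                    pz += dz * s_scat
                    if lab >= 1 and lab <= 5:
                        pl[lab - 1] += s_scat
                    total += s_scat
                    if total > path_cap:
                        fate = 2
                        break
                    dx, dy, dz = _scatter_dir(dx, dy, dz, g7[lab], state)
                    tau = -math.log(1.0 - _rand(state))
                    continue

            # move to the face
            px += dx * tmin
            py += dy * tmin
            pz += dz * tmin
            if lab >= 1 and lab <= 5:
                pl[lab - 1] += tmin
            total += tmin
            if mus > 0.0:
                tau -= mus * tmin
            if total > path_cap:
                fate = 2
                break

            # neighbor voxel across the face
            jx, jy, jz = ix, iy, iz
            if axis == 0:
                step = 1 if dx > 0 else -1
                jx += step
                px = (ix + (1 if step > 0 else 0)) * edge
                da = dx
            elif axis == 1:
                step = 1 if dy > 0 else -1
                jy += step
                py = (iy + (1 if step > 0 else 0)) * edge
                da = dy
            else:
                step = 1 if dz > 0 else -1
                jz += step
                pz = (iz + (1 if step > 0 else 0)) * edge
                da = dz
            inside = (jx >= 0 and jy >= 0 and jz >= 0
                      and jx < nx and jy < ny and jz < nz)
            nlab = labels[jx, jy, jz] if inside else np.int8(0)

            n1 = n7[lab]
            n2 = n7[nlab]
            if n2 != n1:
                ci = abs(da)
                rf = _fresnel_unpolarized(n1, n2, ci)
                if _rand(state) < rf:
                    # reflect off the face, stay in the current voxel
                    if axis == 0:
                        dx = -dx
                    elif axis == 1:
                        dy = -dy
                    else:
                        dz = -dz
                    continue
                # refract across the face (normal along `axis`)
                eta = n1 / n2
                st2 = eta * eta * (1.0 - ci * ci)
                ct = math.sqrt(max(0.0, 1.0 - st2))
                if axis == 0:
                    sgn = 1.0 if dx > 0 else -1.0
                    dy *= eta
                    dz *= eta
                    dx = sgn * ct
                elif axis == 1:
                    sgn = 1.0 if dy > 0 else -1.0
                    dx *= eta
                    dz *= eta
                    dy = sgn * ct
                else:
                    sgn = 1.0 if dz > 0 else -1.0
                    dx *= eta
                    dy *= eta
                    dz = sgn * ct
                nrm = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= nrm
                dy /= nrm
                dz /= nrm

            if (not inside) or nlab == 0:
                # exited into the outer medium: detector test; each
                # detector tallies independently, so overlapping rings are
                # allowed and a photon may be recorded by more than one
                for d in range(nd):
                    if det_mode[d] == 1:
                        # ring around the source on the top surface
                        if pz > edge:
                            continue
                        rx = px - det_pos[d, 0]
                        ry = py - det_pos[d, 1]
                        rho = math.sqrt(rx * rx + ry * ry)
                        if rho < det_r0[d] or rho > det_r1[d]:
                            continue
                    else:
                        rx = px - det_pos[d, 0]
                        ry = py - det_pos[d, 1]
                        rz = pz - det_pos[d, 2]
                        if math.sqrt(rx * rx + ry * ry + rz * rz) \
                                > det_r1[d]:
                            continue
                    # exit direction has a positive dot with the outward
                    # detector normal
                    cosang = (dx * det_norm[d, 0] + dy * det_norm[d, 1]
                              + dz * det_norm[d, 2])
                    if cosang <= 0.0:
                        continue
                    if accept_all == 0 and cosang < cos_amax:
                        continue
                    if cosang > 1.0:
                        cosang = 1.0
                    if n_store < out_det.shape[0]:
                        out_det[n_store] = d
                        for k in range(5):
                            out_pl[n_store, k] = pl[k]
                        out_ang[n_store] = math.acos(cosang)
                        n_store += 1
                        fate = 0
                break

            ix, iy, iz = jx, jy, jz
            lab = nlab

        if fate == 0:
            counts[0] += 1
        elif fate == 1:
            counts[1] += 1
        else:
            counts[2] += 1

    return n_store


# --------------------------------------------------------------------------
# result container and wrappers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RngConfig:
    """Seed plus the stream-splitting scheme: photon i uses a splitmix64
    counter stream keyed on (seed, i), so records are reproducible
    bit-for-bit regardless of execution order."""

    seed: int
    scheme: str = "splitmix64-per-photon"


@dataclass
class WMCResult:
    """Per-detected-photon pathlength records from one white-MC run."""

    det_id: np.ndarray              # (N,) detector index, 0-based
    pathlengths: np.ndarray         # (N, 5) cm in (scalp, skull, csf, gm, wm)
    exit_angle: np.ndarray          # (N,) rad, vs the detector normal
    n_total: int
    n_detectors: int
    musp_combo: dict
    acceptance_na: float
    seed: int
    counts: dict = field(default_factory=dict)
    model_fingerprint: str = ""
    probe_fingerprint: str = ""
    path_cap_cm: float = 300.0

    def __post_init__(self) -> None:
        if len(self.det_id):
            if self.pathlengths.min() < 0:
                raise ValueError("negative pathlength record")
            if np.any(self.pathlengths.sum(axis=1) <= 0):
                raise ValueError("detected photon with zero total pathlength")

    @property
    def n_detected(self) -> np.ndarray:
        """Detected photon count per detector."""
        return np.bincount(self.det_id, minlength=self.n_detectors)

    def filter_acceptance(self, na: float,
                          fiber_n: float = 1.457) -> "WMCResult":
        """Restrict the records to photons within a smaller acceptance
        cone (the low-NA view of a high-NA run)."""
        if na >= 1.0:
            keep = np.ones(len(self.det_id), bool)
        else:
            amax = math.asin(min(na / fiber_n, 1.0))
            keep = self.exit_angle <= amax
        return WMCResult(
            det_id=self.det_id[keep], pathlengths=self.pathlengths[keep],
            exit_angle=self.exit_angle[keep], n_total=self.n_total,
            n_detectors=self.n_detectors, musp_combo=dict(self.musp_combo),
            acceptance_na=na, seed=self.seed, counts=dict(self.counts),
            model_fingerprint=self.model_fingerprint,
            probe_fingerprint=self.probe_fingerprint,
            path_cap_cm=self.path_cap_cm)

    # --- persistence -------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("det_id", data=self.det_id)
            f.create_dataset("pathlengths", data=self.pathlengths)
            f.create_dataset("exit_angle", data=self.exit_angle)
            f.attrs["n_total"] = self.n_total
            f.attrs["n_detectors"] = self.n_detectors
            f.attrs["acceptance_na"] = self.acceptance_na
            f.attrs["seed"] = self.seed
            f.attrs["path_cap_cm"] = self.path_cap_cm
            f.attrs["model_fingerprint"] = self.model_fingerprint
            f.attrs["probe_fingerprint"] = self.probe_fingerprint
            for k, v in self.musp_combo.items():
                f.attrs[f"musp_{k}"] = v
            for k, v in self.counts.items():
                f.attrs[f"count_{k}"] = v

    @classmethod
    def load(cls, path) -> "WMCResult":
        with h5py.File(path, "r") as f:
            musp = {k[5:]: float(v) for k, v in f.attrs.items()
                    if k.startswith("musp_")}
            counts = {k[6:]: int(v) for k, v in f.attrs.items()
                      if k.startswith("count_")}
            return cls(
                det_id=f["det_id"][:], pathlengths=f["pathlengths"][:],
                exit_angle=f["exit_angle"][:],
                n_total=int(f.attrs["n_total"]),
                n_detectors=int(f.attrs["n_detectors"]),
                musp_combo=musp,
                acceptance_na=float(f.attrs["acceptance_na"]),
                seed=int(f.attrs["seed"]), counts=counts,
                model_fingerprint=str(f.attrs["model_fingerprint"]),
                probe_fingerprint=str(f.attrs["probe_fingerprint"]),
                path_cap_cm=float(f.attrs["path_cap_cm"]))


def musp_dict_to_labels(musp_combo: dict, g: float = 0.9,
                        ranges: OPRanges | None = None):
    """Expand a {scalp, skull, csf, gm} reduced-scattering dict to the
    label-indexed mu_s, g and n arrays the kernel consumes.  White matter is
    coupled as mu_s'_WM = 3 mu_s'_GM unless given explicitly."""
    ranges = ranges or OPRanges.default()
    musp = dict(musp_combo)
    musp.setdefault("wm", 3.0 * musp["gm"])
    mus7 = np.zeros(7)
    g7 = np.zeros(7)
    n7 = np.zeros(7)
    n7[LABELS["outer"]] = ranges.n["outer"]
    n7[LABELS["sinus"]] = ranges.n["sinus"]
    for name in COMPARTMENTS:
        lab = LABELS[name]
        gg = ranges.g[name] if g is None else g
        mus7[lab] = musp[name] / (1.0 - gg)
        g7[lab] = gg
        n7[lab] = ranges.n[name]
    return mus7, g7, n7


def _pack_probe(probe: ProbeLayout):
    norm = np.asarray(probe.source_normal_in, float)
    norm = norm / np.linalg.norm(norm)
    # orthonormal tangents
    a = np.array([1.0, 0.0, 0.0])
    if abs(norm @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(norm, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(norm, t1)
    dets = probe.detectors
    det_mode = np.array([1 if d.mode == "ring" else 0 for d in dets],
                        np.int8)
    det_pos = np.array([d.position_cm for d in dets], float)
    det_norm = np.array([d.normal_out for d in dets], float)
    det_r0 = np.array([d.r0_cm for d in dets], float)
    det_r1 = np.array([d.r1_cm for d in dets], float)
    return norm, t1, t2, det_mode, det_pos, det_norm, det_r0, det_r1


def run_white_mc(model: VoxelHeadModel, probe: ProbeLayout, musp_combo: dict,
                 n_photons: int, acceptance_na: float | None = None,
                 rng: RngConfig | int = 0, g: float = 0.9,
                 path_cap_cm: float = 300.0,
                 ranges: OPRanges | None = None) -> WMCResult:
    """Run a zero-absorption (white) MC simulation and record pathlengths.

    ``musp_combo`` maps compartment name -> mu_s' (1/cm) for scalp, skull,
    csf and gm (wm defaults to the 3x gm coupling).  ``acceptance_na``
    defaults to the probe's; NA >= 1 accepts every exit angle (the
    high-throughput mode used for lookup-table construction).  A detector
    with zero detected photons yields an empty record set, not an error.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    seed = rng.seed if isinstance(rng, RngConfig) else int(rng)
    na = probe.acceptance_na if acceptance_na is None else float(acceptance_na)
    mus7, g7, n7 = musp_dict_to_labels(musp_combo, g=g, ranges=ranges)
    norm, t1, t2, det_mode, det_pos, det_norm, det_r0, det_r1 = \
        _pack_probe(probe)
    accept_all = 1 if na >= 1.0 else 0
    cos_amax = math.cos(math.asin(min(na / probe.fiber_n, 1.0)))

    out_det = np.empty(n_photons, np.int32)
    out_pl = np.empty((n_photons, 5), np.float64)
    out_ang = np.empty(n_photons, np.float64)
    counts = np.zeros(4, np.int64)
    n_store = _kernel(
        model.labels, model.boundary_distance_map(), model.edge_cm,
        mus7, g7, n7,
        np.asarray(probe.source_pos_cm, float), norm, t1, t2,
        probe.source_radius_cm, probe.source_na, probe.fiber_n,
        det_mode, det_pos, det_norm, det_r0, det_r1, cos_amax, accept_all,
        int(n_photons), int(seed) & 0x7FFFFFFFFFFFFFFF, float(path_cap_cm),
        out_det, out_pl, out_ang, counts)

    count_dict = {"detected": int(counts[0]), "escaped": int(counts[1]),
                  "capped": int(counts[2]), "specular": int(counts[3])}
    assert sum(count_dict.values()) == n_photons
    return WMCResult(
        det_id=out_det[:n_store].copy(),
        pathlengths=out_pl[:n_store].copy(),
        exit_angle=out_ang[:n_store].copy(),
        n_total=int(n_photons), n_detectors=len(probe.detectors),
        musp_combo=dict(musp_combo), acceptance_na=na, seed=int(seed),
        counts=count_dict, model_fingerprint=model.fingerprint(),
        probe_fingerprint=probe.fingerprint(), path_cap_cm=path_cap_cm)


def mua_dict_to_array(mua_combo: dict) -> np.ndarray:
    """Expand a {scalp, skull, csf, gm[, wm]} absorption dict into the
    compartment-ordered 5-vector, applying the WM = GM/2 coupling when WM
    is not given."""
    mua = dict(mua_combo)
    mua.setdefault("wm", mua["gm"] / 2.0)
    missing = [c for c in COMPARTMENTS if c not in mua]
    if missing:
        raise ValueError(f"missing compartments in mua_combo: {missing}")
    arr = np.array([float(mua[c]) for c in COMPARTMENTS])
    if np.any(arr < 0):
        raise ValueError("mu_a must be >= 0")
    return arr


def reflectance_from_records(result: WMCResult, mua) -> np.ndarray:
    """Microscopic Beer-Lambert reflectance per detector.

    ``mua`` is a compartment dict or a 5-vector ordered (scalp, skull, csf,
    gm, wm), in 1/cm.
    """
    mua5 = mua_dict_to_array(mua) if isinstance(mua, dict) \
        else np.asarray(mua, float)
    if mua5.shape != (5,):
        raise ValueError("mua must have five compartments")
    w = np.exp(-(result.pathlengths @ mua5))
    r = np.bincount(result.det_id, weights=w,
                    minlength=result.n_detectors)
    return r / result.n_total


def run_absorbing_mc(model: VoxelHeadModel, probe: ProbeLayout,
                     mua_combo: dict, musp_combo: dict, n_photons: int,
                     acceptance_na: float | None = None,
                     rng: RngConfig | int = 0, g: float = 0.9,
                     path_cap_cm: float = 300.0,
                     ranges: OPRanges | None = None) -> np.ndarray:
    """Direct absorbing-mode reflectance per detector.

    Trajectories are identical to :func:`run_white_mc` at equal seed
    (continuous absorption weighting never alters the random walk); each
    detected photon contributes exp(-sum_l mu_a,l PL_l).
    """
    res = run_white_mc(model, probe, musp_combo, n_photons,
                       acceptance_na=acceptance_na, rng=rng, g=g,
                       path_cap_cm=path_cap_cm, ranges=ranges)
    return reflectance_from_records(res, mua_combo)


def reflectance_with_error(result: WMCResult, mua):
    """Beer-Lambert reflectance per detector plus its one-sigma Monte
    Carlo standard error (per-photon contribution variance / N)."""
    mua5 = mua_dict_to_array(mua) if isinstance(mua, dict) \
        else np.asarray(mua, float)
    w = np.exp(-(result.pathlengths @ mua5))
    n = result.n_total
    s1 = np.bincount(result.det_id, weights=w,
                     minlength=result.n_detectors)
    s2 = np.bincount(result.det_id, weights=w * w,
                     minlength=result.n_detectors)
    r = s1 / n
    var = np.maximum(s2 / n - r * r, 0.0) / n
    return r, np.sqrt(var)


def mean_partial_pathlength(result: WMCResult, mua, detector: int):
    """Absorption-weighted mean pathlength per compartment (cm) for one
    detector: sum_i w_i PL(i,l) / sum_i w_i with the Beer-Lambert weights.
    Equals -d ln R / d mu_a,l."""
    mua5 = mua_dict_to_array(mua) if isinstance(mua, dict) \
        else np.asarray(mua, float)
    sel = result.det_id == detector
    if not np.any(sel):
        raise ValueError(f"no detected photons at detector {detector}")
    pl = result.pathlengths[sel]
    w = np.exp(-(pl @ mua5))
    return (w[:, None] * pl).sum(axis=0) / w.sum()
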