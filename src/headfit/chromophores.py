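"""Chromophore spectra and tissue-parameter -> optical-property conversion.

The head is modeled as seven compartments (outer medium, scalp, skull, CSF,
gray matter, white matter, frontal sinus).  For scalp, skull and gray matter
the wavelength dependence of the absorption coefficient mu_a is carried by a
small set of chromophores (oxy/deoxy-hemoglobin, water, collagen, melanin)

    mu_a(lam) = 2.303*[eps_HbO(lam)*StO2 + eps_Hb(lam)*(1-StO2)]*tHB
                + sum_i mu_a,i(lam)*C_i

and the reduced (transport) scattering coefficient mu_s' by an inverse power
law mu_s'(lam) = A*lam^-K.  CSF optical properties are fixed spectra taken
from the packaged library; white matter is coupled to gray matter
(mu_a,WM = mu_a,GM/2, mu_s',WM = 3*mu_s',GM); the sinus is an air cavity
(mu_a = mu_s = 0, n = 1).

Units: wavelengths in nm, mu_a and mu_s' in 1/cm, molar extinction in
1/(cm*M) with the base-10 convention (hence the 2.303 factor), tHB in M,
volume fractions dimensionless.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChromophoreLibrary",
    "TissueRecord",
    "TissueParams",
    "OPRanges",
    "CompartmentOPSpectra",
    "OPVector",
    "RangeViolation",
    "LABELS",
    "COMPARTMENTS",
    "FIT_COMPARTMENTS",
    "transport_scattering",
    "inverse_transport_scattering",
    "musp_powerlaw",
    "mua_from_chromophores",
    "params_to_op_spectra",
]

#: voxel label codes shared across the package
LABELS = {
    "outer": 0,
    "scalp": 1,
    "skull": 2,
    "csf": 3,
    "gm": 4,
    "wm": 5,
    "sinus": 6,
}

#: tissue compartments that carry pathlength records (label order 1..5)
COMPARTMENTS = ("scalp", "skull", "csf", "gm", "wm")

#: compartments whose optical properties enter the forward model input
FIT_COMPARTMENTS = ("scalp", "skull", "csf", "gm")


# ---------------------------------------------------------------------------
# chromophore library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromophoreLibrary:
    """Tabulated chromophore spectra on a shared, increasing nm grid."""

    wavelengths: np.ndarray
    eps_HbO: np.ndarray
    eps_Hb: np.ndarray
    mua_water: np.ndarray
    mua_collagen: np.ndarray
    mua_melanin: np.ndarray
    mua_CSF: np.ndarray
    musp_CSF: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, float)
        if w.ndim != 1 or len(w) < 2 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be 1-D strictly increasing")
        for name in ("eps_HbO", "eps_Hb", "mua_water", "mua_collagen",
                     "mua_melanin", "mua_CSF", "musp_CSF"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != w.shape:
                raise ValueError(f"{name} shape does not match grid")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_tsv(cls, path=None) -> "ChromophoreLibrary":
        """Load a library from TSV (defaults to the packaged fixture)."""
        if path is None:
            path = importlib.resources.files("headfit.data") / "chromophores.tsv"
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(float),
            eps_HbO=df["eps_HbO"].to_numpy(float),
            eps_Hb=df["eps_Hb"].to_numpy(float),
            mua_water=df["mua_water"].to_numpy(float),
            mua_collagen=df["mua_collagen"].to_numpy(float),
            mua_melanin=df["mua_melanin"].to_numpy(float),
            mua_CSF=df["mua_CSF"].to_numpy(float),
            musp_CSF=df["musp_CSF"].to_numpy(float),
        )

    def _interp(self, values: np.ndarray, wavelengths) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(wavelengths, float))
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelengths outside library support [{lo}, {hi}] nm; "
                "no extrapolation")
        return np.interp(lam, self.wavelengths, values)

    def sample(self, name: str, wavelengths) -> np.ndarray:
        """Linearly interpolate a spectrum column at the given wavelengths."""
        return self._interp(getattr(self, name), wavelengths)

    def isosbestic_wavelength(self) -> float:
        """Wavelength where eps_HbO crosses eps_Hb (hemoglobin isosbestic)."""
        d = self.eps_HbO - self.eps_Hb
        sign = np.sign(d)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            raise ValueError("extinction spectra do not cross on the grid")
        i = idx[0]
        w0, w1 = self.wavelengths[i], self.wavelengths[i + 1]
        return float(w0 - d[i] * (w1 - w0) / (d[i + 1] - d[i]))


# ---------------------------------------------------------------------------
# tissue parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueRecord:
    """Variable parameters of one fitted tissue plus its fixed fractions.

    tHB : total hemoglobin concentration (M)
    StO2 : tissue oxygen saturation (fraction, 0..1)
    A, K : scattering power-law amplitude (1/cm * nm^K) and exponent
    C_melanin / C_water / C_collagen : chromophore volume fractions
    """

    tHB: float
    StO2: float
    A: float
    K: float
    C_melanin: float = 0.0
    C_water: float = 0.0
    C_collagen: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.StO2 <= 1.0):
            raise ValueError("StO2 must be in [0, 1]")
        if self.tHB < 0:
            raise ValueError("tHB must be >= 0")
        if self.A <= 0:
            raise ValueError("scattering amplitude A must be > 0")
        for nm in ("C_melanin", "C_water", "C_collagen"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    def with_musp_at(self, musp_ref: float, K: float,
                     lam_ref: float = 800.0) -> "TissueRecord":
        """Return a copy with A set so that mu_s'(lam_ref) == musp_ref."""
        return replace(self, A=musp_ref * lam_ref ** K, K=K)


def _default_scalp() -> TissueRecord:
    # C_melanin is a bulk-scalp volume fraction: melanosomes occupy a few
    # percent of a ~0.1 mm epidermis averaged over ~5 mm of scalp, hence
    # the ~1e-4 scale against the 100 % melanin absorption spectrum.
    return TissueRecord(tHB=60e-6, StO2=0.70, A=18.0 * 800 ** 1.2, K=1.2,
                        C_melanin=5e-4, C_water=0.75, C_collagen=0.02)


def _default_skull() -> TissueRecord:
    return TissueRecord(tHB=33e-6, StO2=0.65, A=16.0 * 800 ** 0.9, K=0.9)


def _default_gm() -> TissueRecord:
    return TissueRecord(tHB=80e-6, StO2=0.65, A=11.0 * 800 ** 1.4, K=1.4,
                        C_water=0.75)


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue parameter records for the three fitted compartments.

    The water and collagen volume fractions are fixed model constants
    (scalp: 75 % water + 2 % collagen; gray matter: 75 % water); only
    scalp carries a melanin fraction.  Defaults are physiologically
    plausible mid-range values.
    """

    scalp: TissueRecord = field(default_factory=_default_scalp)
    skull: TissueRecord = field(default_factory=_default_skull)
    gm: TissueRecord = field(default_factory=_default_gm)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueParams":
        return cls(**{k: TissueRecord(**v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "TissueParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# optical-property ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OPRanges:
    """Admissible [min, max] ranges of mu_a / mu_s' per compartment (1/cm),
    plus refractive indices and anisotropy.

    ``fixed`` compartments (CSF, sinus, outer) are never fitted.
    """

    mua: dict
    musp: dict
    n: dict
    g: dict
    fixed: tuple = ("csf", "sinus", "outer")

    def __post_init__(self) -> None:
        for table in (self.mua, self.musp):
            for tissue, (lo, hi) in table.items():
                if not lo < hi:
                    raise ValueError(f"degenerate range for {tissue}: "
                                     f"[{lo}, {hi}]")

    @classmethod
    def default(cls) -> "OPRanges":
        return cls(
            mua={"scalp": (0.1, 0.6), "skull": (0.05, 0.45),
                 "csf": (0.015, 0.1), "gm": (0.05, 0.5),
                 "wm": (0.025, 0.25)},
            musp={"scalp": (5.0, 35.0), "skull": (5.0, 35.0),
                  "csf": (1.0, 3.7), "gm": (5.0, 35.0),
                  "wm": (15.0, 105.0)},
            n={"outer": 1.457, "scalp": 1.4, "skull": 1.4, "csf": 1.4,
               "gm": 1.4, "wm": 1.4, "sinus": 1.0},
            g={"scalp": 0.9, "skull": 0.9, "csf": 0.9, "gm": 0.9, "wm": 0.9,
               "sinus": 0.0},
        )

    @classmethod
    def from_yaml(cls, path) -> "OPRanges":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = cls.default()
        return cls(mua={**base.mua, **d.get("mua", {})},
                   musp={**base.musp, **d.get("musp", {})},
                   n={**base.n, **d.get("n", {})},
                   g={**base.g, **d.get("g", {})})


@dataclass(frozen=True)
class RangeViolation:
    """One optical property exceeding its admissible range at one wavelength."""

    tissue: str
    quantity: str  # "mua" or "musp"
    wavelength: float
    value: float
    bound: float  # the violated bound


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def transport_scattering(mus, g):
    """Reduce mu_s and anisotropy g to the transport coefficient
    mu_s' = mu_s*(1-g)."""
    mus = np.asarray(mus, float)
    g = np.asarray(g, float)
    if np.any(mus < 0):
        raise ValueError("mus must be >= 0")
    if np.any(g < 0) or np.any(g >= 1):
        raise ValueError("g must satisfy 0 <= g < 1")
    return mus * (1.0 - g)


def inverse_transport_scattering(musp, g):
    """Recover mu_s = mu_s'/(1-g); undefined for g >= 1."""
    musp = np.asarray(musp, float)
    g = np.asarray(g, float)
    if np.any(g >= 1):
        raise ValueError("g >= 1: inverse undefined")
    return musp / (1.0 - g)


def musp_powerlaw(A, K, wavelengths):
    """Evaluate mu_s'(lam) = A * lam^-K elementwise (lam in nm)."""
    lam = np.asarray(wavelengths, float)
    if A <= 0:
        raise ValueError("A must be > 0")
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be > 0")
    return A * lam ** (-K)


def mua_from_chromophores(record: TissueRecord, lib: ChromophoreLibrary,
                          wavelengths) -> np.ndarray:
    """Tissue absorption spectrum from the chromophore mixture model."""
    lam = np.atleast_1d(np.asarray(wavelengths, float))
    eps_mix = (lib.sample("eps_HbO", lam) * record.StO2
               + lib.sample("eps_Hb", lam) * (1.0 - record.StO2))
    mua = 2.303 * eps_mix * record.tHB
    mua = mua + record.C_water * lib.sample("mua_water", lam)
    mua = mua + record.C_collagen * lib.sample("mua_collagen", lam)
    mua = mua + record.C_melanin * lib.sample("mua_melanin", lam)
    return mua


# ---------------------------------------------------------------------------
# full spectra container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OPVector:
    """The eight forward-model inputs at a single wavelength:
    (mu_a, mu_s') of scalp, skull, CSF, gray matter, in 1/cm."""

    mua_scalp: float
    mua_skull: float
    mua_csf: float
    mua_gm: float
    musp_scalp: float
    musp_skull: float
    musp_csf: float
    musp_gm: float

    def to_array(self) -> np.ndarray:
        return np.array([self.mua_scalp, self.mua_skull, self.mua_csf,
                         self.mua_gm, self.musp_scalp, self.musp_skull,
                         self.musp_csf, self.musp_gm])

    @classmethod
    def from_array(cls, a) -> "OPVector":
        return cls(*np.asarray(a, float))


@dataclass(frozen=True)
class CompartmentOPSpectra:
    """Per-wavelength, per-compartment optical properties.

    ``mua`` and ``musp`` map compartment name -> spectrum (1/cm) on
    ``wavelengths``; ``violations`` lists range excursions found when the
    spectra were built (used as a soft fitting constraint, not an error).
    """

    wavelengths: np.ndarray
    mua: dict
    musp: dict
    n: dict
    g: dict
    violations: tuple = ()

    def mus(self, tissue: str) -> np.ndarray:
        g = self.g[tissue]
        if g >= 1:
            raise ValueError("g >= 1")
        return np.asarray(self.musp[tissue]) / (1.0 - g)

    def op_vector(self, wavelength: float) -> OPVector:
        """Extract the eight forward-model inputs at one wavelength."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > 1e-9:
            raise ValueError(f"wavelength {wavelength} not in spectra grid")
        return OPVector(
            mua_scalp=self.mua["scalp"][i], mua_skull=self.mua["skull"][i],
            mua_csf=self.mua["csf"][i], mua_gm=self.mua["gm"][i],
            musp_scalp=self.musp["scalp"][i], musp_skull=self.musp["skull"][i],
            musp_csf=self.musp["csf"][i], musp_gm=self.musp["gm"][i])

    def op_matrix(self) -> np.ndarray:
        """(n_wavelengths, 8) matrix of forward-model inputs."""
        return np.column_stack([
            self.mua["scalp"], self.mua["skull"], self.mua["csf"],
            self.mua["gm"], self.musp["scalp"], self.musp["skull"],
            self.musp["csf"], self.musp["gm"]])


def params_to_op_spectra(params: TissueParams, lib: ChromophoreLibrary,
                         ranges: OPRanges, wavelengths) -> CompartmentOPSpectra:
    """Convert tissue parameters to per-compartment OP spectra.

    Scalp/skull/GM come from the chromophore and power-law models, CSF is
    copied from the library, white matter is coupled to gray matter
    (half the absorption, three times the reduced scattering) and the sinus
    is a clear air cavity.  Wavelengths where a derived OP leaves its
    admissible range are reported in ``violations``.
    """
    lam = np.atleast_1d(np.asarray(wavelengths, float))
    mua = {}
    musp = {}
    for tissue in ("scalp", "skull", "gm"):
        rec: TissueRecord = getattr(params, tissue)
        mua[tissue] = mua_from_chromophores(rec, lib, lam)
        musp[tissue] = musp_powerlaw(rec.A, rec.K, lam)
    mua["csf"] = lib.sample("mua_CSF", lam)
    musp["csf"] = lib.sample("musp_CSF", lam)
    mua["wm"] = mua["gm"] / 2.0
    musp["wm"] = 3.0 * musp["gm"]
    mua["sinus"] = np.zeros_like(lam)
    musp["sinus"] = np.zeros_like(lam)

    violations = []
    for tissue in ("scalp", "skull", "gm", "wm"):
        for qty, table in (("mua", mua), ("musp", musp)):
            lo, hi = getattr(ranges, qty)[tissue]
            vals = table[tissue]
            for j in np.nonzero(vals < lo)[0]:
                violations.append(RangeViolation(tissue, qty, lam[j],
                                                 float(vals[j]), lo))
            for j in np.nonzero(vals > hi)[0]:
                violations.append(RangeViolation(tissue, qty, lam[j],
                                                 float(vals[j]), hi))
    return CompartmentOPSpectra(wavelengths=lam, mua=mua, musp=musp,
                                n=dict(ranges.n), g=dict(ranges.g),
                                violations=tuple(violations))


def default_fit_wavelengths(n_low: int = 14, n_high: int = 8) -> np.ndarray:
    """The 22 fitting wavelengths: 700-880 nm with doubled density below
    780 nm where hemoglobin spectral contrast is strongest."""
    return np.concatenate([np.linspace(700.0, 778.0, n_low),
                           np.linspace(792.0, 880.0, n_high)])
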