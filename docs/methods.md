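# Methods

`headfit` quantifies the absorption coefficient μa and transport scattering
coefficient μs′ of scalp, skull and gray matter from multidistance
continuous-wave NIRS reflectance spectra, using voxel-based Monte Carlo
photon transport as the forward physics and a trained surrogate inside an
iterative constrained fit. This note documents the model, its assumptions,
the numerical choices, and what the desk-scale studies shipped with the
package do and do not demonstrate.

## Tissue optical model

The head is a labeled voxel volume (edge 0.93 mm) with seven compartments:
outer medium, scalp, skull, CSF, gray matter (GM), white matter (WM) and an
optional air sinus. Per compartment the model carries μa, μs, the
anisotropy g and refractive index n. All tissues share n = 1.4 and g = 0.9;
the outer medium and the fibers have n = 1.457; the sinus is clear air
(n = 1, μa = μs = 0). Scattering is reduced to the transport coefficient
μs′ = μs (1 − g), assumed to follow the power law μs′(λ) = A λ^−K (λ in nm,
A in cm⁻¹ nmᴷ). Absorption is decomposed over chromophores,

μa(λ) = 2.303 [ε_HbO(λ) StO₂ + ε_Hb(λ) (1 − StO₂)] tHB + Σᵢ μa,ᵢ(λ) Cᵢ,

with molar extinctions ε in cm⁻¹ M⁻¹ (base-10 convention, hence the 2.303),
total hemoglobin tHB in M, oxygen saturation StO₂, and volume fractions Cᵢ
of water, collagen and melanin against their 100 % (v/v) absorption
spectra. Fixed fractions: scalp 75 % water + 2 % collagen (plus a fitted
melanin fraction), GM 75 % water. CSF optical properties are fixed spectra
from the packaged library; WM is coupled to GM as μa,WM = μa,GM/2 and
μs′,WM = 3 μs′,GM, acceptable because WM starts 16–20 mm deep where the
probe's sensitivity is low.

The free parameters of the fit are 13 scalars: (tHB, StO₂, C_melanin,
μs′(800 nm), K) for scalp and (tHB, StO₂, μs′(800 nm), K) for skull and GM.
The scattering law is parameterized by its 800 nm value rather than A to
keep optimizer scaling uniform; A = μs′(800)·800ᴷ. The melanin fraction is
a bulk-scalp volume fraction (bounds 0–1.5 × 10⁻³): melanosomes occupy a
few percent of a ~0.1 mm epidermis diluted over ~5 mm of scalp, against a
100 %-melanin spectrum of order 200 cm⁻¹ at 700 nm. tHB bounds
(≈ 5–260 μM) are set so the derived μa spans its admissible range. Derived
optical properties are constrained to per-compartment ranges
(scalp μa 0.1–0.6, μs′ 5–35; skull 0.05–0.45, 5–35; CSF 0.015–0.1, 1–3.7;
GM 0.05–0.5, 5–35; WM 0.025–0.25, 15–105 cm⁻¹) at every fitted wavelength.

The chromophore library (`data/chromophores.tsv`, 650–1050 nm at 1 nm) is a
PCHIP resampling of literature-level anchor values (hemoglobin per the
standard compiled extinction tables, water per the classic transmission
measurements, collagen per broadband tissue spectroscopy, melanin as the
λ^−3.48 power law). It is a synthetic resampling, not a digitization of any
single published figure; the hemoglobin isosbestic point lands near
800 nm. CSF defaults follow the water shape with an offset
(0.0151 + 0.15 μa,water) and a weak scattering power law, both inside the
fixed CSF ranges and overridable.

## Photon transport

Photons are launched from a fiber-bundle source (disc radius 2.1 mm,
NA 0.39 inside n = 1.457 fiber, Fresnel-refracted into the tissue;
configurable pencil mode) and tracked through the voxel grid. Free paths
are sampled from the local μs; deflections use Henyey–Greenstein sampling
at g = 0.9. Traversal is ray-exact at voxel faces, so per-compartment
pathlengths are exact per segment; interior tissue boundaries are
index-matched and only the outer boundary (1.4 ↔ 1.457) and sinus faces
(1.4 ↔ 1.0) reflect or refract by the unpolarized Fresnel coefficients.
Away from label boundaries the kernel takes free-flight steps inside a
precomputed homogeneity radius (a per-voxel distance transform to the
nearest different label), which avoids face bookkeeping where the mean free
path (≈ 0.003–0.01 cm) is far below the voxel edge. Random numbers come
from counter-based splitmix64 streams keyed on (seed, photon index), so
records are bit-reproducible regardless of execution order.

Transport is "white": absorption never alters a trajectory. Detected
photons store their pathlengths PL(i,l) in the five tissue compartments and
the reflectance for any absorption combination follows from the
microscopic Beer–Lambert law R = Σᵢ exp(−Σ_l μa,l PL(i,l)) / N_total. The
absorbing-mode oracle applies exactly this continuous weighting, making the
two routes identical at equal seed and statistically independent at
different seeds. Photons terminate on exit or when the cumulative path
exceeds a cap (default 300 cm, where the weight at the smallest admissible
μa is negligible; the desk studies use 100 cm since every fitted μa is
≥ 0.05 cm⁻¹, putting truncated weight below e⁻⁵ of a path's contribution,
well under Monte Carlo noise at desk photon budgets).

Detectors are either discs (core radius 0.2 mm, the physical fiber) or —
on flat models — annuli around the source, which azimuthally average the
radially symmetric geometry and multiply the effective collection area by
orders of magnitude at desk photon budgets. Every detector tallies
exiting photons independently, so rings may overlap; the desk studies
widen the long-separation rings (half-widths 0.1–0.5 cm) where photon
flux is lowest, despite the closely spaced 3.0 and 3.35 cm separations.
Forward model and synthetic targets always share the same geometry, so
the radial smearing cancels. Acceptance is
tested against the local surface normal: a photon is kept if its exit angle
(in the n = 1.457 outer medium) is within asin(NA/1.457); NA ≥ 1 accepts
every exit angle (the wide-open acceleration mode). A wide-open run can be
filtered after the fact to any smaller NA because exit angles are stored.

## Forward store and surrogate

White-MC runs are performed once per μs′ combination on a per-compartment
grid; the full-scale grid (scalp 13, skull 9, CSF 4, GM 6 nodes) holds
2808 combinations, the desk grid 3 × 3 × 2 × 3 = 54 spanning the same
ranges. Off-grid reflectance is obtained by separable local-polynomial
interpolation (cubic where four nodes exist, else quadratic/linear) of
log-reflectance across the four μs′ axes, with √μs′ as the abscissa: in
the diffusive regime ln R scales with √(μa μs′_eff), so the square-root
axis nearly linearizes the node values. A refinement study against direct
off-grid simulations showed that a two-node GM axis linearly chords a
convex curve and biases long-separation reflectance upward by tens of
percent, hence the third GM node (5, 16, 35 cm⁻¹) and the √ abscissa;
together they push interpolation bias below the node Monte Carlo noise at
separations up to 3.35 cm. Log-space keeps the interpolant stable over
the ~6 decades spanned by the detectors, and node queries reproduce
stored values exactly. Zero-count readings are replaced by half
the smallest positive reading of the same detector — a "below everything
observed" marker — rather than a fixed count-based floor, because
Beer–Lambert weighted sums are legitimately far below one photon's worth of
reflectance at long separations.

Wide-open collection is converted to the physical NA = 0.12 by a pooled
linear regression of the low/high-NA reflectance ratio on six features
(log reflectance, log detected count, μa and μs′ of scalp and skull), with
predicted ratios clipped into (0, 1]. Constant and perfectly duplicated
features are dropped automatically (with zero absorption, log R and log N
are exact duplicates); an irreducible rank deficiency is an error.

The training set expands the table into (8 optical properties →
6 reflectances) rows: (grid nodes + random in-hull μs′ combinations) ×
random μa combinations, split 75/10/15 % into train/validation/test. At
full scale this is (2808 + 3000) × 3000 = 17.4 million rows; desk studies
use a few hundred μa draws. The surrogate is a fully connected network on
z-scored inputs predicting log-reflectance (hence strictly positive
predictions); the full-scale architecture is 850/550/300/150 hidden units,
the desk default (64, 64). Small tables train with L-BFGS to tolerance;
large ones with Adam and early stopping on the validation split. Inference
is a plain numpy forward pass (> 10⁵ queries/s on one CPU) and serializes
round-trip bit-exactly.

## Inverse fit

Target spectra are calibrated per detector by a linear regression of
model-simulated against measured phantom reflectance, then fitted at 22
wavelengths on 700–880 nm (density doubled below 780 nm where hemoglobin
contrast is strongest; the set is configurable). The objective is the RMS
percent spectral error sqrt(Σ_d Σ_i (Rs/Rm − 1)² / (nd nλ)) over the
fitted detectors. From a presimulated pool of 5000 random valid parameter
sets, the 20 with the smallest spectral error to the target seed
independent SLSQP runs on unit-cube-scaled parameters under bound
constraints plus the nonlinear constraint that all derived OPs stay in
range at every fitted wavelength (12 inequality margins). Results are
sorted by fitted-detector error; fits within 2 % (absolute, the measured
instrument noise level) of the best form the candidate set, and detectors
excluded from the fit act as tie breakers with the same 2 % band. Two or
more survivors are reported as multiple solutions.

## Uncertainty and validation studies

Synthetic test spectra attach multiplicative lognormal noise with the
measured per-detector CVs (3.0, 4.2, 5.1, 5.2, 5.4, 12.1 % at SDS 0.8,
1.5, 2.12, 3, 3.35, 4.5 cm), independent across wavelengths by default
(a correlated-across-wavelength mode emulates coupling drift; the true
spectral correlation of instrument noise is not characterized). The
per-wavelength relative OP errors of every fit pool into one histogram
(multiple solutions as separate points) and yield empirical central
68 %/95 % intervals; pooling rather than wavelength-averaging keeps
scattering power-law slope errors visible in the μs′ bands instead of
letting them cancel. Rank validation min–max-normalizes each target's 20 per-start
OP errors and pools them by spectral-error rank; sensitivity analysis
takes central differences of reflectance with respect to each OP.

The headline validation is the three-layer phantom recovery: a slab with
scalp-like (3.5 mm), skull-like (5 mm) and semi-infinite GM-like layers —
bench-top-style thin layers that keep all three compartments within the
depth range the desk photon budget can sample. (The confidence-interval
studies instead use head-regime thicknesses, scalp 5 mm and skull 7 mm,
whose sensitivity ordering they describe.)
Target spectra at the 22 wavelengths come from the absorbing-MC oracle at
fixed mid-range ground-truth parameters (a physical phantom has known,
controlled OPs; the randomness belongs to transport and fitting). The
pipeline mirrors the in-vivo procedure end to end: lookup table → training
set → surrogate → phantom calibration → pool → 20-start constrained fit →
two-stage solution selection; the figure of merit is the maximum over the
six layer OPs of |mean relative error| across the fitted wavelengths. The
calibration stage (six known "phantoms" simulated on both the oracle and
the surrogate side, four wavelengths each, one per-detector level
regression pooled over wavelengths) is essential, exactly as instrument
calibration is in vivo: it absorbs the per-detector level bias that Monte
Carlo node noise imprints on the surrogate, which would otherwise
masquerade as layer-depth information. Detectors at 0.8–3.0 cm are fitted
and the two longest separations act as tie breakers: at desk photon
budgets the 3.35 and 4.5 cm readings are noise-dominated and would
destabilize the objective, while as tie breakers they still discriminate
between near-degenerate solutions. Both study sides run wide-open
acceptance, so NA conversion does not enter this particular study; it is
validated separately.

Desk-scale problem sizes: 54-node tables at 0.7–1.6 × 10⁵ photons per
node, targets at 1–1.5 × 10⁵ photons per wavelength, calibration runs at
10⁵, pools of 2500–3000, up to 300 SLSQP iterations per start. These
budgets put per-detector forward noise at roughly the few-percent level
at short separations and tens of percent at 4.5 cm, where the
Beer–Lambert weighted effective sample size collapses (a few short-path
photons carry most of the weight).

## Known limitations

- The synthetic head generator reproduces layer ordering, thicknesses,
  curvature and sinus pockets, but not real anatomical inhomogeneity
  (vessels, marrow, scalp sublayers); passing desk studies demonstrates
  the pipeline's internal consistency, not in-vivo accuracy.
- The chromophore fixture is representative, not a certified tabulation;
  quantitative in-vivo use should swap in a laboratory's preferred tables
  via `ChromophoreLibrary.from_tsv`.
- Mean CSF dwell per detected photon *increases* with CSF scattering on
  the layered fixture (a diffusing photon lingers in the thin layer longer
  than a ballistic one); the low-scattering "channeling" effect appears
  instead as enhanced far-detector transport. Claims about CSF should use
  the latter observable.
- Curved-surface exit angles use the crossed voxel face normal, a
  stair-step approximation of the smooth surface.
- Desk-scale interval studies find GM μa, not GM μs′, to be the
  widest-uncertainty property across every noise model and geometry
  tried; scalp μs′ is the tightest. At desk budgets the deep-absorption
  information content, not deep scattering, is the weakest link — the
  full-scale ordering (deep scattering worst) belongs to far larger
  photon budgets on a curved head with CSF.
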