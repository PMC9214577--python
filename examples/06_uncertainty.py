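"""Uncertainty quantification: noisy test spectra, confidence intervals
and detector sensitivity.

Synthetic targets with instrument-level multiplicative noise are fitted
repeatedly; pooled relative errors per optical property yield empirical
68 % / 95 % confidence intervals, and finite-difference sensitivities show
which separations constrain which properties.
"""

import numpy as np

from headfit.chromophores import ChromophoreLibrary
from headfit.forward import MuspGrid, build_lookup_table, \
    generate_training_set
from headfit.head_model import ring_probe
from headfit.inverse import FitTarget, ParamSpace, build_initial_pool, \
    fit_multistart
from headfit.phantom import three_layer_phantom
from headfit.surrogate import train_surrogate
from headfit.uncertainty import (NoiseModel, compile_confidence_intervals,
                                 generate_test_spectra,
                                 sensitivity_analysis)

model = three_layer_phantom()
sds = np.array([0.8, 1.5, 2.12, 3.0, 3.35, 4.5])
probe = ring_probe(model, ring_halfwidth_cm=(0.1, 0.2, 0.3, 0.3, 0.3, 0.5),
                   acceptance_na=1.0)
print("building forward model ...")
table = build_lookup_table(model, probe, MuspGrid.desk_scale(),
                           n_photons=40_000, acceptance_na=1.0,
                           base_seed=9, path_cap_cm=100)
surrogate = train_surrogate(
    generate_training_set(table, n_mua=250, n_musp_extra=40, rng=10),
    seed=2)
space = ParamSpace(lib=ChromophoreLibrary.from_tsv())
pool = build_initial_pool(surrogate, space, n=2000, rng=11)

# 10 targets x 5 noisy replicates with the measured per-detector CVs
spectra = generate_test_spectra(surrogate, space, noise=NoiseModel(),
                                n_param=10, n_noise=5, rng=12)
print(f"fitting {spectra.n_replicates} noisy replicates ...")
fits, truths = [], []
for i in range(spectra.noisy.shape[0]):
    for j in range(spectra.noisy.shape[1]):
        target = FitTarget(wavelengths=spectra.wavelengths,
                           reflectance=spectra.noisy[i, j],
                           fit_detectors=(0, 1, 2, 3, 4),
                           tiebreak_detectors=(5,))
        res = fit_multistart(target, surrogate, pool, space=space,
                             n_starts=5, max_iter=80)
        fits.append(res[0].op_spectra)
        truths.append(spectra.truth_ops[i])

dist = compile_confidence_intervals(fits, truths)
print("\n68 % confidence intervals of the relative OP errors (%):")
for name, iv in dist.intervals.items():
    lo, hi = iv[0.68]
    print(f"  {name:<12s} {lo * 100:+6.1f} .. {hi * 100:+6.1f}")

base = spectra.truth_ops[0][10]   # one mid-band baseline
S = sensitivity_analysis(
    lambda X: surrogate.predict_reflectance(X, warn_out_of_range=False),
    base, perturbation=0.05, op_indices=(0, 3))
print("\nsensitivity dR/R per dOP/OP (columns: mua_scalp, mua_gm):")
for d, row in zip(sds, S):
    print(f"  SDS {d:4.2f} cm : {row[0]:+7.3f}  {row[1]:+7.3f}")
print("\nShort separations answer to scalp absorption, long ones to "
      "cortical absorption;\nscalp scattering has the tightest interval "
      "and the buried layers' absorption\nthe widest - the hardest to "
      "pin down at this photon budget.")
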