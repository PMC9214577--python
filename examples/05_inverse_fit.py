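"""Multi-start constrained curve fitting with multiple-solution selection.

A target spectrum is produced from known tissue parameters, the 20 best
members of a presimulated random pool seed independent constrained fits,
and fits ending within the 2 % noise band of the best are disambiguated by
tie-breaker detectors.
"""

import numpy as np

from headfit.chromophores import ChromophoreLibrary, default_fit_wavelengths
from headfit.forward import MuspGrid, build_lookup_table, \
    generate_training_set
from headfit.head_model import ring_probe
from headfit.inverse import (FitTarget, ParamSpace, build_initial_pool,
                             fit_multistart, select_solutions)
from headfit.phantom import three_layer_phantom
from headfit.surrogate import train_surrogate

model = three_layer_phantom()
sds = np.array([0.8, 1.5, 2.12, 3.0, 3.35, 4.5])
probe = ring_probe(model, ring_halfwidth_cm=(0.1, 0.2, 0.3, 0.3, 0.3, 0.5),
                   acceptance_na=1.0)
print("building forward model (lookup table + surrogate) ...")
table = build_lookup_table(model, probe, MuspGrid.desk_scale(),
                           n_photons=40_000, acceptance_na=1.0,
                           base_seed=6, path_cap_cm=100)
surrogate = train_surrogate(
    generate_training_set(table, n_mua=250, n_musp_extra=40, rng=7),
    seed=1)

space = ParamSpace(lib=ChromophoreLibrary.from_tsv())
lam = default_fit_wavelengths()
pool = build_initial_pool(surrogate, space, n=3000, rng=8)

# a hidden ground truth drawn from the admissible parameter box
rng = np.random.default_rng(5)
true_vec = space.sample_valid(1, rng, lam)[0]
ops = space.op_matrix_batch(true_vec[None], lam)[0]
target = FitTarget(
    wavelengths=lam,
    reflectance=surrogate.predict_reflectance(ops,
                                              warn_out_of_range=False),
    fit_detectors=(0, 1, 2, 3, 4), tiebreak_detectors=(5,))

results = fit_multistart(target, surrogate, pool, space=space,
                         n_starts=20, max_iter=200)
sol = select_solutions(results, threshold=0.02)
best = sol.solutions[0]

print(f"\nbest spectral error : {best.error_fit * 100:.2f} % "
      f"({len(sol.solutions)} solution(s) kept, "
      f"multiple={sol.multiple})")
print("recovered vs true parameter vector (first entries):")
for name, est, tru in list(zip(space.names, best.vector, true_vec))[:6]:
    print(f"  {name:<14s} {est:10.4g}   vs {tru:10.4g}")
print("\nA noiseless self-consistent target is recovered almost exactly; "
      "the spectral\nerror floor reflects the optimizer tolerance, not "
      "model mismatch.")
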