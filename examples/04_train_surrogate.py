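"""Train the neural-network surrogate that replaces Monte Carlo in the
inverse loop.

The lookup table is expanded into (optical properties -> reflectance)
training rows; a small fully connected network learns the map on a log
scale and then answers forward queries about four orders of magnitude
faster than a fresh simulation.
"""

import time

import numpy as np

from headfit.forward import MuspGrid, build_lookup_table, \
    generate_training_set
from headfit.head_model import ring_probe
from headfit.phantom import three_layer_phantom
from headfit.surrogate import train_surrogate

model = three_layer_phantom()
sds = np.array([0.8, 1.5, 2.12, 3.0, 3.35, 4.5])
probe = ring_probe(model, ring_halfwidth_cm=(0.1, 0.2, 0.3, 0.3, 0.3, 0.5),
                   acceptance_na=1.0)

print("building a desk-scale lookup table (36 nodes) ...")
table = build_lookup_table(model, probe, MuspGrid.desk_scale(),
                           n_photons=40_000, acceptance_na=1.0,
                           base_seed=2, path_cap_cm=100)
data = generate_training_set(table, n_mua=250, n_musp_extra=40, rng=4)
print(f"training rows: {data.n_rows} "
      f"(full scale would use {17_424_000:,})")

surrogate = train_surrogate(data, seed=0)
print("per-detector RMS percent error on the held-out test split:")
for det, err in zip(sds, surrogate.metrics["test_rms_percent"]):
    print(f"  SDS {det:4.2f} cm : {err:5.2f} %")

X = data.X[:20_000]
t0 = time.perf_counter()
surrogate.predict_reflectance(X, warn_out_of_range=False)
rate = len(X) / (time.perf_counter() - t0)
print(f"\nthroughput: {rate:,.0f} forward queries/s on one CPU")
print("Errors track the Monte Carlo noise of the underlying grid nodes - "
      "the surrogate\nadds little error of its own and makes iterative "
      "curve fitting practical.")
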