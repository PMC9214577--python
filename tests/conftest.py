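"""Shared fixtures.

The expensive objects (white-MC runs, the phantom lookup table and its
surrogate) are session-scoped and shared across test modules; budgets are
desk-scale: enough photons for the statistical assertions at hand, small
enough to keep the whole suite within a coffee break.
"""

import numpy as np
import pytest
import warnings

from headfit.chromophores import ChromophoreLibrary, OPRanges
from headfit.forward import MuspGrid, build_lookup_table, \
    generate_training_set
from headfit.head_model import VoxelHeadModel, build_synthetic_head, \
    ring_probe
from headfit.inverse import ParamSpace, build_initial_pool
from headfit.mc import run_white_mc
from headfit.phantom import build_phantom_lookup, three_layer_phantom
from headfit.surrogate import train_surrogate

warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")

#: typical head reduced-scattering combination used by several MC fixtures
TYPICAL_MUSP = {"scalp": 18.0, "skull": 16.0, "csf": 2.4, "gm": 11.0}
TYPICAL_MUA = {"scalp": 0.2, "skull": 0.12, "csf": 0.025, "gm": 0.18}


@pytest.fixture(scope="session")
def lib():
    return ChromophoreLibrary.from_tsv()


@pytest.fixture(scope="session")
def ranges():
    return OPRanges.default()


@pytest.fixture(scope="session")
def head_slab():
    """Flat four-layer head model (scalp/skull/CSF/GM/WM)."""
    return build_synthetic_head(dims=(108, 108, 56))


@pytest.fixture(scope="session")
def head_rings(head_slab):
    return ring_probe(head_slab)


@pytest.fixture(scope="session")
def head_wmc(head_slab, head_rings):
    """Shared white-MC run on the head slab, wide-open acceptance."""
    return run_white_mc(head_slab, head_rings, TYPICAL_MUSP,
                        n_photons=150_000, acceptance_na=1.0, rng=42,
                        path_cap_cm=150.0)


@pytest.fixture(scope="session")
def homogeneous_model():
    """Uniform gray-matter block for oracle comparisons."""
    return VoxelHeadModel(labels=np.full((120, 120, 60), 4, np.int8))


@pytest.fixture(scope="session")
def micro_lut(homogeneous_model):
    """Tiny lookup table on the homogeneous block for interpolation and
    NA-conversion unit tests."""
    probe = ring_probe(homogeneous_model, sds_list_cm=(0.8, 1.5, 2.12),
                       ring_halfwidth_cm=0.1, acceptance_na=1.0)
    grid = MuspGrid(scalp=(8.0, 30.0), skull=(8.0, 30.0), csf=(1.0, 3.7),
                    gm=(8.0, 30.0))
    return build_lookup_table(homogeneous_model, probe, grid,
                              n_photons=25_000, acceptance_na=1.0,
                              base_seed=7, path_cap_cm=80.0)


@pytest.fixture(scope="session")
def phantom_bundle(lib, ranges):
    """Lookup table, surrogate and initial pool on the three-layer phantom
    — the backbone shared by the recovery and self-consistency tests."""
    model = three_layer_phantom()
    sds = np.asarray([0.8, 1.5, 2.12, 3.0, 3.35, 4.5])
    probe = ring_probe(model, ring_halfwidth_cm=(0.1, 0.2, 0.3, 0.3, 0.3, 0.5),
                       acceptance_na=1.0)
    table = build_phantom_lookup(model, probe, MuspGrid.desk_scale(),
                                 n_photons=90_000, base_seed=11,
                                 path_cap_cm=100.0)
    data = generate_training_set(table, n_mua=250, n_musp_extra=40, rng=13)
    surrogate = train_surrogate(data, seed=5)
    space = ParamSpace(lib=lib, ranges=ranges)
    pool = build_initial_pool(surrogate, space, n=2500, rng=17)
    return {"model": model, "probe": probe, "table": table,
            "data": data, "surrogate": surrogate, "space": space,
            "pool": pool}


@pytest.fixture(scope="session")
def head_regime_bundle(lib, ranges):
    """Forward bundle on a slab with head-like layer thicknesses (scalp
    5 mm, skull 7 mm, gray matter from 12 mm down) — the geometry whose
    sensitivity ordering the confidence-interval studies refer to."""
    model = three_layer_phantom(thicknesses_mm=(5.0, 7.0))
    probe = ring_probe(model,
                       ring_halfwidth_cm=(0.1, 0.2, 0.3, 0.3, 0.3, 0.5),
                       acceptance_na=1.0)
    table = build_phantom_lookup(model, probe, MuspGrid.desk_scale(),
                                 n_photons=70_000, base_seed=29,
                                 path_cap_cm=100.0)
    data = generate_training_set(table, n_mua=250, n_musp_extra=40, rng=31)
    surrogate = train_surrogate(data, seed=6)
    space = ParamSpace(lib=lib, ranges=ranges)
    pool = build_initial_pool(surrogate, space, n=2500, rng=37)
    return {"model": model, "probe": probe, "table": table,
            "surrogate": surrogate, "space": space, "pool": pool}
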