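"""Shared fixtures.  Expensive sampler runs are session-scoped so several
tests can reuse one trajectory set."""
import numpy as np
import pytest

import mgbind as mg
from mgbind import presets
from mgbind.cvs import CVSpec


@pytest.fixture(scope="session")
def toy_closed():
    return presets.toy_closed_structure()


@pytest.fixture(scope="session")
def toy_open():
    return presets.toy_open_structure()


@pytest.fixture(scope="session")
def double_well_run():
    """Full desk-scale WTMetaD run on the 5 kJ/mol-gap double well."""
    dw = presets.double_well_gap5()
    cvs = [CVSpec(kind="raw_coordinate", name="x", index=0)]
    bias, params, n_walkers = presets.double_well_sampler(seed=2024)
    trajs, bias = mg.run_wtmetad(dw, cvs, bias, params, n_walkers)
    return {"landscape": dw, "cvs": cvs, "trajs": trajs, "bias": bias}


@pytest.fixture(scope="session")
def binding_run():
    """Full desk-scale WTMetaD run on the two-anchor binding landscape."""
    land = presets.binding_landscape()
    cvs = presets.binding_cvs()
    bias, params, n_walkers = presets.binding_sampler(seed=2024)
    trajs, bias = mg.run_wtmetad(land, cvs, bias, params, n_walkers)
    return {"landscape": land, "cvs": cvs, "trajs": trajs, "bias": bias}


@pytest.fixture(scope="session")
def binding_reference_pmf():
    """Quadrature ground-truth PMF along L1 for the binding landscape."""
    land = presets.binding_landscape()
    cvs = presets.binding_cvs()
    grid = presets.binding_pmf_grid()
    ref = mg.reference_fes_by_quadrature(land, grid, [cvs[0]], spacing=0.02)
    centers = grid.centers()[0]
    vals = ref.free_energy
    mask = (centers >= 2.0) & (centers <= 2.5) & np.isfinite(vals)
    pmf = mg.PMFProfile("L1", centers, vals - vals[mask].mean())
    return pmf
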