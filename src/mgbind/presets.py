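"""Shipped fixture landscapes and toy structures.

These presets define the study conditions used throughout the tests and
the demo pipeline: a 1D double well for estimator calibration, and a
"binding landscape" — a particle confined in a flat-bottom cylinder
approaching a pair of carboxyl-like anchors 0.3 nm apart — mirroring the
protein-site geometry (cylinder radius 0.9 nm, wall constant 1e5
kJ mol^-1 nm^-2, RT = 2.577 kJ/mol, bound region L < 0.4 nm, unbound
window 2.0-2.5 nm).
"""
from __future__ import annotations

import numpy as np

from .constants import RT_310
from .cvs import CVSpec
from .landscapes import ModelPotentialSpec, make_toy_tetramer
from .restraints import RestraintSpec

#: Deep-well depth (kJ/mol) giving exactly a 5.0 kJ/mol basin
#: free-energy gap against a 10 kJ/mol partner well of equal width at
#: RT = 2.577 (frozen from one-time 1D quadrature root-finding).
DOUBLE_WELL_GAP5_DEPTH = 15.92945458655307

DOUBLE_WELL_MINIMA = (0.25, 2.25)
DOUBLE_WELL_WIDTH = 0.15
DOUBLE_WELL_WALLS = (-0.3, 2.8)


def double_well(depths=(10.0, 10.0), widths=DOUBLE_WELL_WIDTH,
                RT: float = RT_310) -> ModelPotentialSpec:
    """1D double well with minima at 0.25 and 2.25 nm and soft end walls."""
    w = np.broadcast_to(np.atleast_1d(widths), (2,))
    return ModelPotentialSpec(
        kind="double_well_1d",
        anchors=np.array([[DOUBLE_WELL_MINIMA[0]], [DOUBLE_WELL_MINIMA[1]]]),
        depths=np.asarray(depths, float),
        widths=np.array(w, float),
        restraint=RestraintSpec(R_cyl=0.0, K_res=1e5,
                                axial_range=DOUBLE_WELL_WALLS),
        temperature_RT=RT,
    )


def double_well_gap5(RT: float = RT_310) -> ModelPotentialSpec:
    """Double well engineered to a 5.0 kJ/mol basin free-energy gap."""
    return double_well(depths=(DOUBLE_WELL_GAP5_DEPTH, 10.0), RT=RT)


# ----------------------------------------------------------------------
# 3D binding landscapes

#: Anchor separation mimicking the two carboxyl carbons of the site, nm.
ANCHOR_SEPARATION = 0.3
BINDING_R_CYL = 0.9
BINDING_K_RES = 1.0e5
BINDING_AXIAL_RANGE = (-0.3, 2.7)
BINDING_WELL_DEPTH = 14.0
BINDING_WELL_WIDTH = 0.12
BINDING_REPULSION = 0.06


def binding_anchors() -> np.ndarray:
    half = ANCHOR_SEPARATION / 2
    return np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])


def binding_landscape(depths=(BINDING_WELL_DEPTH, BINDING_WELL_DEPTH),
                      RT: float = RT_310,
                      hydration: bool = False) -> ModelPotentialSpec:
    """Two-anchor binding landscape in a flat-bottom cylinder along +y.

    The particle (the "cation") diffuses inside a cylinder of radius
    0.9 nm along the y axis, with a bound basin at the anchors near the
    origin and a bulk-like unbound region out to y ~ 2.7 nm.  With
    ``hydration=True`` a 4th auxiliary coordinate mimics the water
    coordination number, relaxing from 6 in bulk toward 4 at the site.
    """
    kind = "two_anchor_3d_hydration" if hydration else "two_anchor_3d"
    return ModelPotentialSpec(
        kind=kind,
        anchors=binding_anchors(),
        depths=np.asarray(depths, float),
        widths=np.full(2, BINDING_WELL_WIDTH),
        repulsion_radius=BINDING_REPULSION,
        hydration_coupling=1.0 if hydration else 0.0,
        h_bulk=6.0,
        k_h=20.0,
        restraint=RestraintSpec(axis=[0.0, 1.0, 0.0], R_cyl=BINDING_R_CYL,
                                K_res=BINDING_K_RES,
                                axial_range=BINDING_AXIAL_RANGE),
        temperature_RT=RT,
    )


def binding_cvs(hydration: bool = False) -> list:
    """CVs of the binding landscape: L1, L2 (+ CN_W-like h)."""
    anchors = binding_anchors()
    cvs = [CVSpec(kind="distance_to_anchor", name="L1", anchor=anchors[0]),
           CVSpec(kind="distance_to_anchor", name="L2", anchor=anchors[1])]
    if hydration:
        cvs.append(CVSpec(kind="raw_coordinate", name="CNW", index=3))
    return cvs


# ----------------------------------------------------------------------
# desk-scale sampler configurations (the shipped study conditions)

from .grids import GridSpec          # noqa: E402
from .sampling import BiasState, SamplerParams  # noqa: E402

#: Hill widths: 0.05 nm for distance CVs, 0.1 for the hydration CV.
HILL_WIDTH_DISTANCE = 0.05
HILL_WIDTH_CNW = 0.1
BIAS_FACTOR = 5.0

DOUBLE_WELL_WALKERS = 16
BINDING_WALKERS = 16


def double_well_grid() -> GridSpec:
    return GridSpec.uniform_1d("x", -0.3, 2.8, 124)


def double_well_sampler(seed: int):
    """(bias, params, n_walkers) for the 1D double-well fixture."""
    cache = GridSpec.uniform_1d("x", -0.5, 3.0, 350)
    bias = BiasState(n_cv=1, gamma=BIAS_FACTOR,
                     default_widths=[HILL_WIDTH_DISTANCE], cache_grid=cache)
    params = SamplerParams(dt=2e-4, friction=1.0, n_steps=400_000,
                           deposit_stride=500, seed=seed)
    return bias, params, DOUBLE_WELL_WALKERS


def binding_pmf_grid() -> GridSpec:
    return GridSpec.uniform_1d("L1", 0.0, 2.6, 130)


def binding_fes2d_grid() -> GridSpec:
    return GridSpec(["L1", "L2"], [0.0, 0.0], [2.8, 2.8], [140, 140])


def binding_sampler(seed: int, hydration: bool = False):
    """(bias, params, n_walkers) for the binding landscape."""
    n_cv = 3 if hydration else 2
    names = ["L1", "L2"] + (["CNW"] if hydration else [])
    mins = [0.0, 0.0] + ([3.0] if hydration else [])
    maxs = [3.3, 3.3] + ([7.0] if hydration else [])
    nb = [220, 220] + ([40] if hydration else [])
    widths = [HILL_WIDTH_DISTANCE] * 2 + ([HILL_WIDTH_CNW] if hydration else [])
    cache = GridSpec(names, mins, maxs, nb)
    bias = BiasState(n_cv=n_cv, gamma=BIAS_FACTOR, default_widths=widths,
                     cache_grid=cache)
    params = SamplerParams(dt=2e-4, friction=1.0, n_steps=300_000,
                           deposit_stride=500, seed=seed)
    return bias, params, BINDING_WALKERS


# ----------------------------------------------------------------------
# toy structures mirroring closed vs open site geometry

def toy_closed_structure():
    """C4 tetramer with a per-chain DD pair at 1.05 nm (site formed)."""
    return make_toy_tetramer(4, [("ASP", "ASP", 1.05)])


def toy_open_structure():
    """C4 tetramer with the same DD pair expanded to 1.25 nm (site lost)."""
    return make_toy_tetramer(4, [("ASP", "ASP", 1.25)])
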