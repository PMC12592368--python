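"""Synthetic binding landscapes with brute-force reference free energies.

The toy systems emulate a divalent cation diffusing inside a restraining
cylinder toward one or two attractive "carboxyl" anchors: a sum of
isotropic Gaussian wells plus an r^-12 soft-core repulsion, an optional
auxiliary hydration coordinate ``h`` (a harmonically tethered scalar
whose rest value drops as the particle approaches an anchor, standing in
for the water coordination number of the cation), and a flat-bottom
cylindrical restraint.  Everything is analytically integrable on a dense
grid, so every downstream estimator can be checked against quadrature.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import RT_310
from .cvs import cv_values
from .grids import GridSpec
from .restraints import RestraintSpec, flat_bottom_energy_gradient
from .structure import Structure, AtomRecord, place_atom

KINDS = ("double_well_1d", "two_anchor_3d", "two_anchor_3d_hydration")


@dataclass
class ModelPotentialSpec:
    """Parameters of a toy binding potential.

    anchors:
        Anchor positions; shape ``(n, 1)`` for the 1D double well,
        ``(n, 3)`` otherwise (nm).
    depths, widths:
        Gaussian well depth (kJ/mol, >= 0) and width (nm, > 0) per anchor.
    repulsion_radius:
        Soft-core radius of the ``(r_rep/r)^12`` repulsion per anchor, nm;
        zero disables it.
    hydration_coupling:
        Drop of the hydration rest value contributed by each anchor's
        Gaussian envelope (dimensionless; only for the hydration kind).
    h_bulk, k_h:
        Bulk rest value of ``h`` and its tether constant (kJ/mol per unit^2).
    restraint:
        Optional :class:`RestraintSpec` confining the particle.
    temperature_RT:
        Thermal energy RT, kJ/mol (default 2.577, i.e. 310 K).
    """

    kind: str
    anchors: np.ndarray
    depths: np.ndarray
    widths: np.ndarray
    repulsion_radius: float = 0.0
    hydration_coupling: float = 0.0
    h_bulk: float = 6.0
    k_h: float = 20.0
    restraint: RestraintSpec | None = None
    temperature_RT: float = RT_310

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        self.anchors = np.atleast_2d(np.asarray(self.anchors, dtype=float))
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if np.any(self.depths < 0):
            raise ValueError("well depths must be >= 0")
        if np.any(self.widths <= 0):
            raise ValueError("well widths must be > 0")
        if self.repulsion_radius < 0:
            raise ValueError("repulsion_radius must be >= 0")
        nsp = 1 if self.kind == "double_well_1d" else 3
        if self.anchors.shape[1] != nsp:
            raise ValueError(f"{self.kind} anchors must be {nsp}-dimensional")

    @property
    def ndim_space(self) -> int:
        return 1 if self.kind == "double_well_1d" else 3

    @property
    def ndim(self) -> int:
        return self.ndim_space + (1 if self.kind == "two_anchor_3d_hydration" else 0)


def _check_dims(spec: ModelPotentialSpec, coords: np.ndarray):
    if coords.shape[-1] != spec.ndim:
        raise ValueError(
            f"{spec.kind} expects {spec.ndim}-dimensional coordinates, "
            f"got {coords.shape[-1]}")


def potential_and_gradient(spec: ModelPotentialSpec, coords) -> tuple:
    """Batched potential energy (kJ/mol) and gradient.

    ``coords`` has shape ``(..., ndim)``; returns ``(U, dU/dx)`` of
    shapes ``(...,)`` and ``(..., ndim)``.  Includes the restraint
    energy when the point lies outside the flat-bottom region.
    """
    c = np.asarray(coords, dtype=float)
    _check_dims(spec, c)
    nsp = spec.ndim_space
    space = c[..., :nsp]

    diff = space[..., None, :] - spec.anchors            # (..., n, nsp)
    d = np.linalg.norm(diff, axis=-1)                    # (..., n)
    env = np.exp(-d**2 / (2.0 * spec.widths**2))         # Gaussian envelopes
    u = -np.sum(spec.depths * env, axis=-1)
    # dU_well/dx = depth * env * (r/w^2) * rhat  (summed over anchors)
    coef = spec.depths * env / spec.widths**2            # (..., n)
    g_space = np.sum(coef[..., None] * diff, axis=-2)

    if spec.repulsion_radius > 0:
        dd = np.maximum(d, 1e-6)
        rep = (spec.repulsion_radius / dd) ** 12
        u = u + np.sum(rep, axis=-1)
        rcoef = -12.0 * rep / dd**2                      # d rep / dr * 1/r
        g_space = g_space + np.sum(rcoef[..., None] * diff, axis=-2)

    g = np.zeros_like(c)
    g[..., :nsp] = g_space

    if spec.kind == "two_anchor_3d_hydration":
        h = c[..., nsp]
        h_rest = spec.h_bulk - spec.hydration_coupling * np.sum(env, axis=-1)
        dev = h - h_rest
        u = u + 0.5 * spec.k_h * dev**2
        g[..., nsp] += spec.k_h * dev
        # h_rest depends on position through the envelopes
        denv_dx = -(env / spec.widths**2)[..., None] * diff   # (..., n, nsp)
        dhrest_dx = -spec.hydration_coupling * np.sum(denv_dx, axis=-2)
        g[..., :nsp] += -spec.k_h * dev[..., None] * dhrest_dx

    if spec.restraint is not None:
        if nsp == 1:
            # 1D systems: interpret the axial flat-bottom range as walls on x
            if spec.restraint.axial_range is not None:
                lo, hi = spec.restraint.axial_range
                x = space[..., 0]
                ex = np.where(x < lo, x - lo, np.where(x > hi, x - hi, 0.0))
                u = u + 0.5 * spec.restraint.K_res * ex**2
                g[..., 0] += spec.restraint.K_res * ex
        else:
            e_r, g_r = flat_bottom_energy_gradient(space, spec.restraint)
            u = u + e_r
            g[..., :nsp] += g_r
    return u, g


def eval_potential(spec: ModelPotentialSpec, coords) -> float:
    """Potential energy at one point (kJ/mol); see :func:`potential_and_gradient`."""
    u, _ = potential_and_gradient(spec, np.asarray(coords, dtype=float))
    return float(u) if np.ndim(u) == 0 else u


# ----------------------------------------------------------------------
# brute-force reference FES

@dataclass
class ReferenceFES:
    """Quadrature ground-truth free energy on a CV grid (minimum = 0)."""

    grid: GridSpec
    free_energy: np.ndarray
    method: str = "quadrature"
    normalization: str = "minimum set to zero"
    warnings: list = field(default_factory=list)


def _integration_domain(spec: ModelPotentialSpec, grid: GridSpec) -> list:
    """Per-dimension (lo, hi) bounds where the Boltzmann weight is non-negligible."""
    RT = spec.temperature_RT
    bounds = []
    if spec.ndim_space == 1:
        lo = float(np.min(spec.anchors)) - 5 * float(np.max(spec.widths))
        hi = float(np.max(spec.anchors)) + 5 * float(np.max(spec.widths))
        if spec.restraint is not None and spec.restraint.axial_range is not None:
            delta = np.sqrt(2 * RT * np.log(1e8) / spec.restraint.K_res)
            lo = min(lo, spec.restraint.axial_range[0] - delta)
            hi = max(hi, spec.restraint.axial_range[1] + delta)
        bounds.append((lo, hi))
    else:
        r = spec.restraint
        if r is None:
            lo = spec.anchors.min() - 5 * spec.widths.max()
            hi = spec.anchors.max() + 5 * spec.widths.max()
            bounds.extend([(lo, hi)] * 3)
        else:
            delta = np.sqrt(2 * RT * np.log(1e8) / r.K_res)
            # integration box aligned with the restraint axis frame
            rad = r.R_cyl + delta
            if r.axial_range is not None:
                alo, ahi = r.axial_range[0] - delta, r.axial_range[1] + delta
            else:
                alo = grid.mins.min() - 1.0
                ahi = grid.maxs.max() + 1.0
            bounds.extend([(alo, ahi), (-rad, rad), (-rad, rad)])
    if spec.kind == "two_anchor_3d_hydration":
        sigma_h = np.sqrt(RT / spec.k_h)
        h_lo = spec.h_bulk - spec.hydration_coupling * len(spec.depths) - 5 * sigma_h
        h_hi = spec.h_bulk + 5 * sigma_h
        bounds.append((h_lo, h_hi))
    return bounds


def reference_fes_by_quadrature(spec: ModelPotentialSpec, grid: GridSpec,
                                cv_definition: list, spacing: float = 0.02,
                                h_points: int = 33) -> ReferenceFES:
    """Ground-truth FES by dense-grid numerical integration.

    Evaluates ``F(s) = -RT ln \\int delta(CV(x)-s) exp(-U(x)/RT) dx`` by
    Boltzmann-weighting every point of a dense configuration grid and
    histogramming the CV values onto ``grid``; the minimum is shifted to
    zero.  A warning is recorded in the result provenance when the
    requested ``spacing`` is too coarse to resolve the well widths.
    """
    if spacing <= 0:
        raise ValueError("quadrature spacing must be > 0")
    warnings = []
    if spacing > float(np.min(spec.widths)) / 2:
        warnings.append(
            f"quadrature spacing {spacing} nm exceeds half the narrowest well "
            f"width {float(np.min(spec.widths))}; FES may be under-resolved")

    RT = spec.temperature_RT
    bounds = _integration_domain(spec, grid)
    axes = []
    nsp = spec.ndim_space
    for i, (lo, hi) in enumerate(bounds):
        if i < nsp:
            n = max(int(np.ceil((hi - lo) / spacing)) + 1, 4)
        else:
            n = h_points
        axes.append(np.linspace(lo, hi, n))

    # The spatial integration box is expressed in the restraint frame
    # (axis-aligned); rotate to lab coordinates when needed.
    if nsp == 3 and spec.restraint is not None:
        r = spec.restraint
        a = r.axis
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ a) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, trial)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        frame = np.column_stack([a, e1, e2])  # local -> lab
        origin = r.origin
    else:
        frame = np.eye(nsp)
        origin = np.zeros(nsp)

    edges = grid.edges()
    hist = np.zeros(grid.shape)
    # chunk over the first axis to bound memory
    rest_axes = axes[1:]
    mesh_rest = np.meshgrid(*rest_axes, indexing="ij") if rest_axes else []
    for x0 in axes[0]:
        if rest_axes:
            pts_local = np.stack(
                [np.full(mesh_rest[0].shape, x0)] + list(mesh_rest), axis=-1)
        else:
            pts_local = np.array([[x0]])
        flat = pts_local.reshape(-1, pts_local.shape[-1])
        lab = np.empty_like(flat)
        lab[:, :nsp] = flat[:, :nsp] @ frame.T + origin
        if flat.shape[1] > nsp:
            lab[:, nsp:] = flat[:, nsp:]
        u, _ = potential_and_gradient(spec, lab)
        w = np.exp(-(u - 0.0) / RT)
        s = cv_values(cv_definition, lab)
        h, _ = np.histogramdd(s, bins=edges, weights=w)
        hist += h

    with np.errstate(divide="ignore", invalid="ignore"):
        fes = -RT * np.log(np.where(hist > 0, hist, np.nan))
    fes = fes - np.nanmin(fes)
    return ReferenceFES(grid=grid, free_energy=fes, warnings=warnings)


def basin_free_energy_difference(centers: np.ndarray, fes: np.ndarray,
                                 split: float, RT: float = RT_310) -> float:
    """F(right basin) - F(left basin) from a 1D profile.

    Basin free energies are ``-RT ln sum(exp(-F/RT)) * dx`` over the grid
    points on each side of ``split`` (NaN cells ignored).
    """
    centers = np.asarray(centers, float)
    f = np.asarray(fes, float)
    left = (centers < split) & np.isfinite(f)
    right = (centers >= split) & np.isfinite(f)
    if not left.any() or not right.any():
        raise ValueError("both basins must contain finite FES values")
    zl = np.sum(np.exp(-f[left] / RT))
    zr = np.sum(np.exp(-f[right] / RT))
    return float(-RT * np.log(zr) + RT * np.log(zl))


# ----------------------------------------------------------------------
# toy structures

_SIDE_CHAIN = {"ASP": ("CG", "OD1", "OD2"), "GLU": ("CG", "CD", "OE1", "OE2")}


def _build_residue(res_name: str, ca_pos_nm: np.ndarray, frame: np.ndarray) -> list:
    """Minimal all-atom residue (backbone + Cbeta/Cgamma stubs) at a Calpha.

    Geometry is built in Angstrom by internal coordinates and converted to
    nm; ``frame`` (3x3) orients the residue.
    """
    ca = np.zeros(3)
    n = ca + np.array([1.458, 0.0, 0.0])
    c = place_atom(n + np.array([0, 1, 0]), n, ca, 1.525, 111.0, 120.0)
    o = place_atom(n, ca, c, 1.231, 120.5, -45.0)
    atoms = {"N": ("N", n), "CA": ("C", ca), "C": ("C", c), "O": ("O", o)}
    if res_name != "GLY":
        cb = place_atom(c, n, ca, 1.530, 110.5, -122.0)
        atoms["CB"] = ("C", cb)
        if res_name in _SIDE_CHAIN:
            cg = place_atom(n, ca, cb, 1.520, 114.0, 180.0)  # chi1 anti
            atoms["CG"] = ("C", cg)
            if res_name == "ASP":
                od1 = place_atom(ca, cb, cg, 1.250, 119.0, -30.0)
                od2 = place_atom(ca, cb, cg, 1.250, 119.0, 150.0)
                atoms["OD1"] = ("O", od1)
                atoms["OD2"] = ("O", od2)
            else:  # GLU
                cd = place_atom(ca, cb, cg, 1.520, 114.0, 180.0)
                oe1 = place_atom(cb, cg, cd, 1.250, 119.0, -30.0)
                oe2 = place_atom(cb, cg, cd, 1.250, 119.0, 150.0)
                atoms.update({"CD": ("C", cd), "OE1": ("O", oe1), "OE2": ("O", oe2)})
    out = []
    for name, (elem, pos_a) in atoms.items():
        pos_nm = ca_pos_nm + (frame @ pos_a) / 10.0
        out.append((name, elem, pos_nm))
    return out


def _rotation_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_toy_tetramer(n_chains: int, pair_geometry: list,
                      ring_radius: float = 2.0) -> Structure:
    """Symmetric toy oligomer realising prescribed Calpha-Calpha pairs.

    ``pair_geometry`` is a list of ``(residue_type_a, residue_type_b,
    ca_distance_nm)`` tuples; each pair is placed once per chain and the
    chains are related by C_n rotational symmetry about z.  Residue types
    outside {ASP, GLU, LYS} are built as ALA stubs.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    allowed = {"ASP", "GLU", "LYS"}
    atoms: list = []
    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    for k, cid in enumerate(chain_ids):
        rot = _rotation_z(2 * np.pi * k / n_chains)
        for j, (ta, tb, dist) in enumerate(pair_geometry):
            if dist < 0:
                raise ValueError("Calpha distance must be >= 0")
            na = ta if ta in allowed else "ALA"
            nb = tb if tb in allowed else "ALA"
            ca_a = rot @ np.array([ring_radius, 0.0, 1.5 * j])
            ca_b = rot @ np.array([ring_radius, dist, 1.5 * j])
            num_a, num_b = 100 + 10 * j, 105 + 10 * j
            for name, num, ca in ((na, num_a, ca_a), (nb, num_b, ca_b)):
                for atom_name, elem, pos in _build_residue(name, ca, rot):
                    atoms.append(AtomRecord(atom_name, elem, name, num, cid,
                                            "", 1.0, pos))
    return Structure(atoms=atoms)
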