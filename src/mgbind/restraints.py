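"""Flat-bottom restraints confining the cation in the toy systems.

The sampling volume mimics the setup used for cation-binding free energy
calculations: the mobile particle is free inside a cylinder of radius
``R_cyl`` around a declared axis and feels a harmonic wall (force constant
``K_res``) outside.  Optional flat-bottom caps along the axis bound the
otherwise infinite cylinder, playing the role of the simulation box.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("restraint axis must be a non-zero vector")
    return v / n


@dataclass
class RestraintSpec:
    """Cylindrical flat-bottom (or point-harmonic) restraint.

    Parameters
    ----------
    axis:
        Unit vector of the cylinder axis (normalised on construction).
    R_cyl:
        Flat-bottom radius, nm.  Zero collapses the cylinder to a line.
    K_res:
        Harmonic wall force constant, kJ mol^-1 nm^-2.
    kind:
        ``flat_bottom_cylinder`` or ``harmonic_point``.
    origin:
        Point on the axis (or the harmonic centre), nm.
    axial_range:
        Optional ``(lo, hi)`` flat-bottom interval along the axis, nm.
        Outside it the same ``K_res`` wall applies axially.
    """

    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    R_cyl: float = 0.9
    K_res: float = 1.0e5
    kind: str = "flat_bottom_cylinder"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axial_range: tuple | None = None

    def __post_init__(self):
        self.axis = _unit(self.axis)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.R_cyl < 0:
            raise ValueError("R_cyl must be >= 0")
        if self.K_res <= 0:
            raise ValueError("K_res must be > 0")
        if self.kind not in ("flat_bottom_cylinder", "harmonic_point"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")


def flat_bottom_energy(position, restraint: RestraintSpec) -> float:
    """Restraint energy at ``position`` (kJ/mol).

    Zero inside the flat-bottom region, ``1/2 K_res (r - R_cyl)^2``
    outside; value and first derivative are continuous at the wall.
    """
    e, _ = flat_bottom_energy_gradient(np.asarray(position, float), restraint)
    return float(e) if np.ndim(position) == 1 else e


def flat_bottom_energy_gradient(positions: np.ndarray, restraint: RestraintSpec):
    """Batched restraint energy and gradient.

    ``positions`` has shape ``(..., 3)``; returns ``(E, dE/dx)`` with
    shapes ``(...,)`` and ``(..., 3)``.
    """
    p = np.asarray(positions, dtype=float)
    rel = p - restraint.origin
    if restraint.kind == "harmonic_point":
        e = 0.5 * restraint.K_res * np.sum(rel**2, axis=-1)
        g = restraint.K_res * rel
        return e, g

    a = restraint.axis
    t = rel @ a                      # axial coordinate
    perp = rel - t[..., None] * a
    r = np.linalg.norm(perp, axis=-1)
    excess = np.maximum(r - restraint.R_cyl, 0.0)
    e = 0.5 * restraint.K_res * excess**2
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.where(r[..., None] > 0, perp / np.maximum(r, 1e-300)[..., None], 0.0)
    g = restraint.K_res * excess[..., None] * rhat

    if restraint.axial_range is not None:
        lo, hi = restraint.axial_range
        ax_excess = np.where(t < lo, t - lo, np.where(t > hi, t - hi, 0.0))
        e = e + 0.5 * restraint.K_res * ax_excess**2
        g = g + restraint.K_res * ax_excess[..., None] * a
    return e, g
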