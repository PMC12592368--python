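"""Collective variables (CVs) over toy-sampler configurations.

A configuration is a point in sampler space: 1 coordinate for the 1D
double well, 3 for a particle in a cylinder, 4 when the auxiliary
hydration coordinate ``h`` is present (the 4th component).  CVs mirror
the ones biased in cation-binding metadynamics: distances from the
cation to carboxyl carbons (L, L1, L2) and a hydration coordination
number (CN_W).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def coordination_number(distances, r0: float) -> float:
    """Smooth coordination count via the rational switching function.

    Each distance contributes ``(1-(r/r0)^6)/(1-(r/r0)^12)``, a smooth,
    monotonically decreasing switch that equals 1 at contact and has a
    removable singularity at ``r = r0`` whose limit is 1/2.  The
    algebraically identical total form ``1/(1+(r/r0)^6)`` is used, which
    evaluates the limit automatically.
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    return float(np.sum(1.0 / (1.0 + (d / r0) ** 6)))


def _switch_and_derivative(d: np.ndarray, r0: float):
    """Per-distance switch value and d(switch)/d(distance)."""
    x6 = (d / r0) ** 6
    s = 1.0 / (1.0 + x6)
    ds = -6.0 * x6 / (d + 1e-300) * s**2
    return s, ds


@dataclass
class CVSpec:
    """One collective variable.

    kind:
        ``distance_to_anchor`` -- Euclidean distance from the particle
        (first 3 coordinates, or 1 in 1D) to ``anchor``;
        ``coordination_number`` -- switching-function sum over distances
        to each point in ``anchor`` (an ``(n, 3)`` array) with radius
        ``r0``;
        ``raw_coordinate`` -- the sampler coordinate at ``index`` (used
        for the 1D position and for the auxiliary hydration coordinate).
    """

    kind: str
    name: str
    anchor: np.ndarray | None = None
    index: int | None = None
    r0: float | None = None

    def __post_init__(self):
        if self.kind not in ("distance_to_anchor", "coordination_number",
                             "raw_coordinate"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float)
        if self.kind == "coordination_number":
            if self.r0 is None or self.r0 <= 0:
                raise ValueError("coordination_number CV requires r0 > 0")
            self.anchor = np.atleast_2d(self.anchor)
        if self.kind == "distance_to_anchor" and self.anchor is None:
            raise ValueError("distance_to_anchor CV requires an anchor")
        if self.kind == "raw_coordinate" and self.index is None:
            raise ValueError("raw_coordinate CV requires an index")

    # -- evaluation --------------------------------------------------

    def value(self, coords: np.ndarray) -> np.ndarray:
        """CV value; ``coords`` has shape ``(..., ndim)``."""
        c = np.asarray(coords, dtype=float)
        if self.kind == "raw_coordinate":
            return c[..., self.index]
        space = c[..., : self.anchor.shape[-1]] if self.anchor.ndim == 1 else c[..., :3]
        if self.kind == "distance_to_anchor":
            return np.linalg.norm(space - self.anchor, axis=-1)
        # coordination_number
        d = np.linalg.norm(space[..., None, :] - self.anchor, axis=-1)
        s, _ = _switch_and_derivative(d, self.r0)
        return np.sum(s, axis=-1)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        """d(CV)/d(coords), shape ``(..., ndim)``."""
        c = np.asarray(coords, dtype=float)
        g = np.zeros_like(c)
        if self.kind == "raw_coordinate":
            g[..., self.index] = 1.0
            return g
        nsp = self.anchor.shape[-1] if self.anchor.ndim == 1 else 3
        space = c[..., :nsp]
        if self.kind == "distance_to_anchor":
            diff = space - self.anchor
            d = np.linalg.norm(diff, axis=-1, keepdims=True)
            g[..., :nsp] = diff / np.maximum(d, 1e-12)
            return g
        diff = space[..., None, :] - self.anchor            # (..., n, 3)
        d = np.linalg.norm(diff, axis=-1)                   # (..., n)
        _, ds = _switch_and_derivative(d, self.r0)
        unit = diff / np.maximum(d, 1e-12)[..., None]
        g[..., :nsp] = np.sum(ds[..., None] * unit, axis=-2)
        return g


    def value_and_gradient(self, coords: np.ndarray) -> tuple:
        """Fused ``(value, gradient)`` avoiding duplicate distance work."""
        c = np.asarray(coords, dtype=float)
        if self.kind == "distance_to_anchor":
            nsp = self.anchor.shape[-1]
            diff = c[..., :nsp] - self.anchor
            d = np.sqrt(np.sum(diff * diff, axis=-1))
            g = np.zeros_like(c)
            g[..., :nsp] = diff / np.maximum(d, 1e-12)[..., None]
            return d, g
        return self.value(c), self.gradient(c)


def cv_values(cvs: list, coords: np.ndarray) -> np.ndarray:
    """Stack CV values, shape ``(..., n_cv)``."""
    return np.stack([cv.value(coords) for cv in cvs], axis=-1)
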