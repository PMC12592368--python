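"""Desk-scale well-tempered metadynamics on synthetic landscapes.

Overdamped (Brownian) Langevin dynamics with Gaussian bias deposition
along collective variables, shared multiple-walker bias, and flat-bottom
restraints.  The integrator is a toy replacement for atomistic MD: the
estimators downstream (reweighting, MFEP, binding free energy), not the
integrator, are the interesting part, so timestep and friction are
toy-scale parameters with no physical units attached beyond nm / kJ/mol.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import RT_310
from .cvs import CVSpec, coordination_number, cv_values  # noqa: F401 (re-export)
from .landscapes import ModelPotentialSpec, potential_and_gradient
from .restraints import RestraintSpec, flat_bottom_energy  # noqa: F401 (re-export)


def well_tempered_height(h0: float, bias_at_center: float, gamma: float,
                         RT: float = RT_310) -> float:
    """Height of the next deposited hill under the well-tempered rule.

    ``h = h0 * exp(-V_bias(s) / ((gamma - 1) RT))``: heights decay
    geometrically as a point accumulates bias; ``gamma -> inf`` recovers
    standard metadynamics.
    """
    if gamma <= 1:
        raise ValueError("bias factor gamma must be > 1")
    return float(h0 * np.exp(-bias_at_center / ((gamma - 1.0) * RT)))


@dataclass
class GaussianHill:
    time: float
    center: np.ndarray
    widths: np.ndarray
    height: float

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, float))
        self.widths = np.atleast_1d(np.asarray(self.widths, float))
        if np.any(self.widths <= 0):
            raise ValueError("hill widths must be > 0")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")


def _multilinear_many(axes: list, arrays: list, pts: np.ndarray) -> list:
    """Multilinear interpolation of several ``arrays`` (values on ``axes``
    nodes) at ``pts`` of shape ``(N, d)``, sharing the index/fraction
    computation; points outside the box are clamped."""
    from itertools import product

    d = len(axes)
    idx, frac = [], []
    for k, ax in enumerate(axes):
        x = np.minimum(np.maximum(pts[:, k], ax[0]), ax[-1])
        i = np.minimum(np.maximum(np.searchsorted(ax, x) - 1, 0), len(ax) - 2)
        idx.append(i)
        frac.append((x - ax[i]) / (ax[i + 1] - ax[i]))
    outs = [np.zeros(len(pts)) for _ in arrays]
    for corner in product((0, 1), repeat=d):
        w = frac[0] if corner[0] else 1.0 - frac[0]
        ii = [idx[0] + corner[0]]
        for k in range(1, d):
            w = w * (frac[k] if corner[k] else 1.0 - frac[k])
            ii.append(idx[k] + corner[k])
        ii = tuple(ii)
        for arr, out in zip(arrays, outs):
            out += w * arr[ii]
    return outs


def _multilinear(axes: list, arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return _multilinear_many(axes, [arr], pts)[0]


class BiasState:
    """Accumulated metadynamics bias: an ordered list of Gaussian hills.

    Defaults mirror the sampling scheme used for cation binding:
    bias factor ``gamma = 5`` and base height ``h0 = 0.3 RT``; per-CV
    hill widths default to 0.05 nm for distances and 0.1 for
    coordination-number-like CVs (set via ``default_widths``).

    When ``cache_grid`` (a :class:`~mgbind.grids.GridSpec` covering the
    reachable CV range) is given, the bias and its gradient are
    accumulated on grid nodes at deposition time and evaluated by
    multilinear interpolation — a resolved-grid approximation used for
    speed.  :meth:`exact_bias` always performs the exact hill summation.
    """

    def __init__(self, n_cv: int, gamma: float = 5.0, h0: float | None = None,
                 default_widths=None, RT: float = RT_310,
                 truncate_sigmas: float | None = None, cache_grid=None):
        if gamma <= 1:
            raise ValueError("bias factor gamma must be > 1")
        self.n_cv = int(n_cv)
        self.gamma = float(gamma)
        self.RT = float(RT)
        self.h0 = float(0.3 * RT if h0 is None else h0)
        if default_widths is None:
            default_widths = np.full(self.n_cv, 0.05)
        self.default_widths = np.atleast_1d(np.asarray(default_widths, float))
        self.truncate_sigmas = truncate_sigmas
        self._times: list = []
        self._centers: list = []
        self._widths: list = []
        self._heights: list = []
        self._cache_axes = None
        self._cache_grid = cache_grid
        if cache_grid is not None:
            if cache_grid.ndim != self.n_cv:
                raise ValueError("cache grid dimension must equal n_cv")
            self._cache_axes = cache_grid.edges()
            shape = tuple(len(a) for a in self._cache_axes)
            self._cache_v = np.zeros(shape)
            self._cache_g = np.zeros((self.n_cv,) + shape)

    # -- bookkeeping -------------------------------------------------

    @property
    def hills(self) -> list:
        return [GaussianHill(t, c, w, h) for t, c, w, h in
                zip(self._times, self._centers, self._widths, self._heights)]

    def __len__(self) -> int:
        return len(self._heights)

    def add_hill(self, time: float, center, height: float, widths=None) -> None:
        center = np.atleast_1d(np.asarray(center, float))
        widths = self.default_widths if widths is None else \
            np.atleast_1d(np.asarray(widths, float))
        if center.shape != (self.n_cv,) or widths.shape != (self.n_cv,):
            raise ValueError("hill center/widths dimension mismatch")
        if height < 0:
            raise ValueError("hill height must be >= 0")
        self._times.append(float(time))
        self._centers.append(center)
        self._widths.append(widths)
        self._heights.append(float(height))
        self._arrays_cache = None
        if self._cache_axes is not None:
            self._deposit_on_cache(center, widths, float(height))

    def _deposit_on_cache(self, center, widths, height) -> None:
        axes = self._cache_axes
        mesh = np.meshgrid(*axes, indexing="ij")
        z2 = sum(((m - c) / w) ** 2 for m, c, w in zip(mesh, center, widths))
        g = height * np.exp(-0.5 * z2)
        self._cache_v += g
        for k in range(self.n_cv):
            self._cache_g[k] += -g * (mesh[k] - center[k]) / widths[k] ** 2

    _arrays_cache = None

    def _arrays(self):
        if not self._heights:
            return None
        if self._arrays_cache is None:
            self._arrays_cache = (np.asarray(self._centers),
                                  np.asarray(self._widths),
                                  np.asarray(self._heights))
        return self._arrays_cache

    # -- evaluation (exact summation over hills) ---------------------

    def bias(self, s) -> np.ndarray:
        """Total bias V_b(s); ``s`` has shape ``(..., n_cv)``."""
        s = np.atleast_1d(np.asarray(s, float))
        scalar = s.ndim == 1
        if not self._heights:
            out = np.zeros(s.shape[:-1])
            return float(out) if scalar else out
        if self._cache_axes is not None:
            out = _multilinear(self._cache_axes, self._cache_v,
                               s.reshape(-1, self.n_cv)).reshape(s.shape[:-1])
            return float(out) if scalar else out
        centers, widths, heights = self._arrays()
        flat = s.reshape(-1, self.n_cv)
        out = np.empty(len(flat))
        # chunk the (points x hills) temporary to bound memory
        chunk = max(1, int(2e7) // max(len(centers), 1))
        for i in range(0, len(flat), chunk):
            z = (flat[i:i + chunk, None, :] - centers) / widths
            e2 = np.sum(z**2, axis=-1)
            if self.truncate_sigmas is not None:
                mask = e2 <= self.truncate_sigmas**2
                g = np.where(mask, np.exp(np.where(mask, -0.5 * e2, 0.0)), 0.0)
            else:
                g = np.exp(-0.5 * e2)
            out[i:i + chunk] = g @ heights
        out = out.reshape(s.shape[:-1])
        return float(out) if scalar else out

    def with_cache(self, cache_grid) -> "BiasState":
        """Copy of this bias with hills re-deposited on a grid cache."""
        out = BiasState(self.n_cv, gamma=self.gamma, h0=self.h0,
                        default_widths=self.default_widths, RT=self.RT,
                        truncate_sigmas=self.truncate_sigmas,
                        cache_grid=cache_grid)
        for t, c, w, h in zip(self._times, self._centers, self._widths,
                              self._heights):
            out.add_hill(t, c, h, w)
        return out

    def value_and_gradient(self, s: np.ndarray) -> tuple:
        """Fused ``(V_b(s), dV_b/ds)`` for 2D sample arrays (N, n_cv)."""
        s = np.asarray(s, float)
        if not self._heights:
            return np.zeros(s.shape[:-1]), np.zeros_like(s)
        if self._cache_axes is not None:
            flat = s.reshape(-1, self.n_cv)
            outs = _multilinear_many(
                self._cache_axes,
                [self._cache_v] + [self._cache_g[k] for k in range(self.n_cv)],
                flat)
            v = outs[0].reshape(s.shape[:-1])
            g = np.stack(outs[1:], axis=-1).reshape(s.shape)
            return v, g
        return self.bias(s), self.bias_gradient(s)

    def exact_bias(self, s) -> np.ndarray:
        """Exact hill summation regardless of any grid cache."""
        axes, self._cache_axes = self._cache_axes, None
        try:
            return self.bias(s)
        finally:
            self._cache_axes = axes

    def bias_gradient(self, s) -> np.ndarray:
        """dV_b/ds, shape ``(..., n_cv)``."""
        s = np.atleast_1d(np.asarray(s, float))
        if not self._heights:
            return np.zeros_like(s)
        if self._cache_axes is not None:
            flat = s.reshape(-1, self.n_cv)
            out = np.stack([_multilinear(self._cache_axes, self._cache_g[k], flat)
                            for k in range(self.n_cv)], axis=-1)
            return out.reshape(s.shape)
        centers, widths, heights = self._arrays()
        z = (s[..., None, :] - centers) / widths
        g = np.exp(-0.5 * np.sum(z**2, axis=-1))            # (..., H)
        coef = -(heights * g)[..., None] * z / widths       # (..., H, n_cv)
        return np.sum(coef, axis=-2)


@dataclass
class SamplerParams:
    """Integrator settings.  ``dt`` and ``friction`` are toy-scale.

    ``max_drift`` caps the magnitude of the deterministic displacement
    per step (nm).  The stiff flat-bottom walls (K ~ 1e5) are far too
    steep for explicit Euler-Maruyama at any useful ``dt``; the cap
    turns them into effectively hard walls while leaving the dynamics
    inside the flat-bottom region untouched (forces there are orders of
    magnitude below the cap threshold).
    """

    dt: float = 2e-4
    friction: float = 1.0
    RT: float = RT_310
    n_steps: int = 50_000
    deposit_stride: int = 250
    seed: int = 0
    sample_stride: int = 1
    max_drift: float = 0.02

    def __post_init__(self):
        if self.dt <= 0 or self.friction <= 0 or self.RT <= 0:
            raise ValueError("dt, friction and RT must be > 0")
        if self.max_drift <= 0:
            raise ValueError("max_drift must be > 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for the stochastic sampler")


@dataclass
class Trajectory:
    walker_id: int
    steps: np.ndarray
    coords: np.ndarray | None
    cv_values: np.ndarray
    bias: np.ndarray
    params: SamplerParams | None = None
    cv_names: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def run_wtmetad(potential: ModelPotentialSpec, cvs: list, bias: BiasState,
                params: SamplerParams, n_walkers: int = 1,
                init_positions=None) -> tuple:
    """Multiple-walker well-tempered metadynamics run.

    All walkers are advanced with Euler-Maruyama overdamped Langevin
    steps on ``potential + shared bias (+ restraints)`` and deposit into
    one shared :class:`BiasState` every ``deposit_stride`` steps in a
    fixed round-robin order.  Bit-for-bit reproducible for a given
    ``(seed, n_walkers, deposit_stride)``.

    Returns ``(trajectories, bias)`` where ``trajectories`` is one
    :class:`Trajectory` per walker.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    ndim = potential.ndim
    n_cv = len(cvs)
    if bias.n_cv != n_cv:
        raise ValueError("BiasState dimension does not match the CV list")
    rng = np.random.default_rng(params.seed)

    if init_positions is None:
        pos = _default_init(potential, n_walkers)
    else:
        pos = np.array(init_positions, dtype=float).reshape(n_walkers, ndim)

    dt, fric, RT = params.dt, params.friction, params.RT
    noise_scale = np.sqrt(2.0 * RT * dt / fric)
    n_rec = params.n_steps // params.sample_stride
    rec_steps = np.empty((n_walkers, n_rec), dtype=int)
    rec_coords = np.empty((n_walkers, n_rec, ndim))
    rec_cvs = np.empty((n_walkers, n_rec, n_cv))
    rec_bias = np.empty((n_walkers, n_rec))
    i_rec = 0

    for step in range(1, params.n_steps + 1):
        u, grad_u = potential_and_gradient(potential, pos)
        cv_vg = [cv.value_and_gradient(pos) for cv in cvs]
        s = np.stack([v for v, _ in cv_vg], axis=-1)         # (W, n_cv)
        v_bias, dv_ds = bias.value_and_gradient(s)

        if step % params.sample_stride == 0 and i_rec < n_rec:
            rec_steps[:, i_rec] = step
            rec_coords[:, i_rec] = pos
            rec_cvs[:, i_rec] = s
            rec_bias[:, i_rec] = v_bias
            i_rec += 1

        if step % params.deposit_stride == 0 and bias.h0 > 0:
            for w in range(n_walkers):                       # round-robin
                h = well_tempered_height(bias.h0, bias.bias(s[w]),
                                         bias.gamma, RT)
                bias.add_hill(step * dt, s[w], h)
            _, dv_ds = bias.value_and_gradient(s)            # refresh forces

        force = -grad_u
        for k in range(n_cv):
            force -= dv_ds[:, k : k + 1] * cv_vg[k][1]
        drift = (dt / fric) * force
        norm = np.sqrt(np.sum(drift * drift, axis=-1, keepdims=True))
        scale = np.where(norm > params.max_drift,
                         params.max_drift / np.maximum(norm, 1e-300), 1.0)
        pos = pos + drift * scale + noise_scale * rng.standard_normal(pos.shape)
        if not np.all(np.isfinite(pos)):
            bad = np.argwhere(~np.isfinite(pos))[0, 0]
            raise FloatingPointError(
                f"non-finite coordinate for walker {bad} at step {step}")

    names = [cv.name for cv in cvs]
    trajs = [Trajectory(w, rec_steps[w, :i_rec], rec_coords[w, :i_rec],
                        rec_cvs[w, :i_rec], rec_bias[w, :i_rec], params, names)
             for w in range(n_walkers)]
    return trajs, bias


def _default_init(potential: ModelPotentialSpec, n_walkers: int) -> np.ndarray:
    """Spread walkers between the anchors and the far end of the restraint."""
    ndim = potential.ndim
    pos = np.zeros((n_walkers, ndim))
    if potential.ndim_space == 1:
        lo = float(np.min(potential.anchors))
        hi = float(np.max(potential.anchors))
        pos[:, 0] = np.linspace(lo, hi, n_walkers + 2)[1:-1]
    else:
        r = potential.restraint
        if r is not None and r.axial_range is not None:
            ts = np.linspace(0.3, 0.8, n_walkers) * (r.axial_range[1] - 0.2)
            for w in range(n_walkers):
                pos[w, :3] = r.origin + ts[w] * r.axis
        else:
            pos[:, :3] = potential.anchors.mean(axis=0) + 0.5
    if potential.kind == "two_anchor_3d_hydration":
        pos[:, -1] = potential.h_bulk
    return pos
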