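"""Free-energy surfaces from biased trajectories: reweighting, projection,
PMF extraction and block-analysis error bars.

The reweighting convention is final-bias (time-independent) weighting:
after discarding an initial burn-in, each retained sample ``s_t`` is
weighted by ``w ∝ exp(+V_b(s_t)/RT)`` with ``V_b`` the bias at the end of
the run.  With an identically zero bias this reduces exactly to the
plain histogram.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import RT_310
from .grids import GridSpec
from .sampling import BiasState, Trajectory


@dataclass
class FESGrid:
    """Free energy on a CV grid; unvisited cells are NaN, never zero."""

    grid: GridSpec
    free_energy: np.ndarray
    RT: float = RT_310
    provenance: dict = field(default_factory=dict)
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.free_energy.shape != self.grid.shape:
            raise ValueError("free energy array shape does not match grid")


@dataclass
class PMFProfile:
    cv_name: str
    centers: np.ndarray
    values: np.ndarray
    zero_convention: str = "mean over unbound window = 0"

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float)
        self.values = np.asarray(self.values, float)
        if self.centers.shape != self.values.shape:
            raise ValueError("centers and values must have the same length")


@dataclass
class BlockAnalysisResult:
    block_counts: np.ndarray
    block_sizes: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    plateau_value: float
    plateau_sem: float
    plateau_block_count: int


# ----------------------------------------------------------------------

def _collect_samples(trajectories, discard):
    """Concatenate CV samples after discarding the burn-in per trajectory."""
    samples = []
    for traj in ([trajectories] if isinstance(trajectories, Trajectory)
                 else list(trajectories)):
        cvs = traj.cv_values
        n = len(cvs)
        if isinstance(discard, float):
            if not 0 <= discard < 1:
                raise ValueError("discard fraction must be in [0, 1)")
            n0 = int(np.floor(discard * n))
        else:
            n0 = int(discard)
        if n0 >= n:
            raise ValueError("discard interval removes all samples")
        samples.append(cvs[n0:])
    return np.concatenate(samples, axis=0)


def reweighting_weights(samples: np.ndarray, bias: BiasState | None,
                        RT: float) -> np.ndarray:
    """Final-bias weights ``w ∝ exp(+V_b(s)/RT)``, stabilised and unit-mean."""
    if bias is None or len(bias) == 0:
        return np.ones(len(samples))
    v = bias.bias(samples)
    w = np.exp((v - v.max()) / RT)
    return w / w.mean()


def reweight_to_fes(trajectories, bias: BiasState | None, grid: GridSpec,
                    discard=0.25, RT: float = RT_310) -> FESGrid:
    """Reweight biased CV samples onto ``grid``.

    ``discard`` is an initial fraction (float < 1) or sample count (int)
    dropped from the beginning of every trajectory before reweighting.
    Returns a :class:`FESGrid` with minimum zero; provenance records the
    per-cell counts and the effective sample size.
    """
    s = _collect_samples(trajectories, discard)
    if s.shape[1] != grid.ndim:
        raise ValueError("trajectory CV dimension does not match grid")
    w = reweighting_weights(s, bias, RT)
    edges = grid.edges()
    hist, _ = np.histogramdd(s, bins=edges, weights=w)
    counts, _ = np.histogramdd(s, bins=edges)
    if hist.sum() == 0:
        raise ValueError("no samples fall inside the grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        fes = -RT * np.log(np.where(hist > 0, hist, np.nan))
    fes = fes - np.nanmin(fes)
    ess = float(w.sum() ** 2 / np.sum(w**2))
    return FESGrid(grid=grid, free_energy=fes, RT=RT, counts=counts,
                   provenance={"n_samples": len(s), "discard": discard,
                               "effective_sample_size": ess,
                               "n_hills": 0 if bias is None else len(bias)})


def project_fes(fes: FESGrid, keep_dims) -> FESGrid:
    """Boltzmann projection onto a subset of CVs, re-zeroed.

    ``F_proj = -RT ln sum_marginalised exp(-F/RT)``; missing (NaN) cells
    are excluded from the sum.
    """
    if not keep_dims:
        raise ValueError("keep_dims must name at least one CV")
    idx = [fes.grid.axis_index(d) if isinstance(d, str) else int(d)
           for d in keep_dims]
    drop = tuple(i for i in range(fes.grid.ndim) if i not in idx)
    with np.errstate(invalid="ignore"):
        boltz = np.exp(-fes.free_energy / fes.RT)
    boltz = np.nan_to_num(boltz, nan=0.0)
    marg = boltz.sum(axis=drop) if drop else boltz
    # restore requested axis order
    kept_order = [i for i in range(fes.grid.ndim) if i in idx]
    perm = [kept_order.index(i) for i in idx]
    marg = np.transpose(marg, perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -fes.RT * np.log(np.where(marg > 0, marg, np.nan))
    f = f - np.nanmin(f)
    sub = fes.grid.subgrid(keep_dims)
    return FESGrid(grid=sub, free_energy=f, RT=fes.RT,
                   provenance=dict(fes.provenance, projected_from=fes.grid.cv_names))


def pmf_along_cv(fes: FESGrid, cv_name: str, unbound_window: tuple) -> PMFProfile:
    """1D PMF along one CV, zeroed over the unbound window.

    Projects the FES onto ``cv_name`` and shifts the profile so that the
    mean over grid centers inside ``unbound_window = (lo, hi)`` is zero.
    """
    proj = project_fes(fes, [cv_name])
    centers = proj.grid.centers()[0]
    values = proj.free_energy
    lo, hi = unbound_window
    mask = (centers >= lo) & (centers <= hi) & np.isfinite(values)
    if not mask.any():
        raise ValueError("unbound window contains no visited PMF points")
    return PMFProfile(cv_name=cv_name, centers=centers,
                      values=values - values[mask].mean())


def pmf_from_weighted_samples(samples: np.ndarray, weights: np.ndarray,
                              grid: GridSpec, unbound_window: tuple,
                              RT: float = RT_310) -> PMFProfile:
    """1D PMF directly from weighted CV samples (used by block analysis)."""
    if grid.ndim != 1:
        raise ValueError("pmf_from_weighted_samples needs a 1D grid")
    hist, _ = np.histogram(samples, bins=grid.edges()[0], weights=weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -RT * np.log(np.where(hist > 0, hist, np.nan))
    centers = grid.centers()[0]
    lo, hi = unbound_window
    mask = (centers >= lo) & (centers <= hi) & np.isfinite(f)
    if not mask.any():
        raise ValueError("unbound window contains no visited PMF points")
    return PMFProfile(cv_name=grid.cv_names[0], centers=centers,
                      values=f - f[mask].mean())


def fes_from_csv(path, RT: float = RT_310) -> FESGrid:
    """Rebuild a :class:`FESGrid` from a long-format CSV.

    Expects one column per CV (grid-center values) plus ``fes_kj_mol``,
    as written by the pipeline; the grid is inferred from the unique
    sorted center values.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cv_names = [c for c in df.columns if c != "fes_kj_mol"]
    centers = [np.sort(df[c].unique()) for c in cv_names]
    steps = [c[1] - c[0] for c in centers]
    grid = GridSpec(cv_names,
                    [c[0] - s / 2 for c, s in zip(centers, steps)],
                    [c[-1] + s / 2 for c, s in zip(centers, steps)],
                    [len(c) for c in centers])
    f = np.full(grid.shape, np.nan)
    idx = tuple(np.searchsorted(c, df[n].to_numpy())
                for c, n in zip(centers, cv_names))
    f[idx] = df["fes_kj_mol"].to_numpy()
    return FESGrid(grid=grid, free_energy=f, RT=RT)


# ----------------------------------------------------------------------

def block_analysis(series, block_counts, functional=None,
                   plateau_rel_tol: float = 0.2) -> BlockAnalysisResult:
    """Blocked error estimate of a trajectory functional.

    The retained ``series`` (an array of per-sample records) is split
    into ``k`` contiguous equal blocks for each requested count
    (truncating the remainder); ``functional`` maps one block to a
    scalar (default: the mean).  The mean and SEM across blocks are
    reported per count; the plateau value/SEM are those at the largest
    block size (the smallest usable block count).  A block whose
    functional is undefined (NaN, e.g. a short block that never visits a
    required CV window) is dropped from that count; counts with fewer
    than two defined blocks are skipped.
    """
    series = np.asarray(series)
    n = len(series)
    if functional is None:
        functional = lambda b: float(np.mean(b))
    counts, sizes, means, sems = [], [], [], []
    for k in sorted(int(k) for k in block_counts):
        if k < 2:
            raise ValueError("block counts must be >= 2")
        if k > n:
            continue  # skipped with warning semantics: unusable count
        size = n // k
        vals = np.array([functional(series[i * size:(i + 1) * size])
                         for i in range(k)])
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            continue
        counts.append(k)
        sizes.append(size)
        means.append(float(vals.mean()))
        sems.append(float(vals.std(ddof=1) / np.sqrt(len(vals))))
    if not counts:
        raise ValueError("series shorter than every requested block count")
    counts = np.asarray(counts)
    sizes = np.asarray(sizes)
    means = np.asarray(means)
    sems = np.asarray(sems)
    i_plateau = int(np.argmax(sizes))  # largest block size
    return BlockAnalysisResult(counts, sizes, means, sems,
                               float(means[i_plateau]), float(sems[i_plateau]),
                               int(counts[i_plateau]))
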