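"""Regular collective-variable grids shared by the FES machinery."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GridSpec:
    """Regular grid over one or more collective variables.

    Each CV ``i`` spans ``[mins[i], maxs[i])`` in ``n_bins[i]`` half-open
    bins; samples landing exactly on the global upper edge are assigned to
    the last bin.
    """

    cv_names: list
    mins: np.ndarray
    maxs: np.ndarray
    n_bins: np.ndarray

    def __post_init__(self):
        self.cv_names = list(self.cv_names)
        self.mins = np.atleast_1d(np.asarray(self.mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(self.maxs, dtype=float))
        self.n_bins = np.atleast_1d(np.asarray(self.n_bins, dtype=int))
        if not (len(self.cv_names) == len(self.mins) == len(self.maxs) == len(self.n_bins)):
            raise ValueError("cv_names, mins, maxs, n_bins must have equal length")
        if np.any(self.maxs <= self.mins):
            raise ValueError("grid requires max > min for every CV")
        if np.any(self.n_bins < 2):
            raise ValueError("grid requires n_bins >= 2")

    @property
    def ndim(self) -> int:
        return len(self.cv_names)

    @property
    def shape(self) -> tuple:
        return tuple(int(n) for n in self.n_bins)

    def edges(self) -> list:
        return [np.linspace(lo, hi, n + 1)
                for lo, hi, n in zip(self.mins, self.maxs, self.n_bins)]

    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges()]

    def spacing(self) -> np.ndarray:
        return (self.maxs - self.mins) / self.n_bins

    def axis_index(self, cv_name: str) -> int:
        try:
            return self.cv_names.index(cv_name)
        except ValueError:
            raise KeyError(f"no CV named {cv_name!r} in grid {self.cv_names}")

    def subgrid(self, keep: list) -> "GridSpec":
        idx = [self.axis_index(n) if isinstance(n, str) else int(n) for n in keep]
        return GridSpec([self.cv_names[i] for i in idx], self.mins[idx],
                        self.maxs[idx], self.n_bins[idx])

    @staticmethod
    def uniform_1d(cv_name: str, lo: float, hi: float, n_bins: int) -> "GridSpec":
        return GridSpec([cv_name], [lo], [hi], [n_bins])
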