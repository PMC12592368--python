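"""Standard binding free energy from a PMF, with restraint-volume and
ionic-strength corrections and block-analysis errors.

The headline quantity is assembled as

    dG0 = dG_PMF + dG_V + dG_I

where dG_PMF integrates the Boltzmann weight of the 1D PMF over the
unbound versus bound regions, dG_V references the sampled unbound volume
(the flat-bottom cylinder cross-section S_u times the unbound window
length l_u) to the 1 M standard-state volume V0 = 1.661 nm^3, and dG_I
removes the ionic-strength dependence via the limiting Debye-Hueckel
law.  The decomposition identity holds exactly by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEBYE_HUCKEL_A_310, RT_310, V0_STANDARD
from .fes import (BlockAnalysisResult, GridSpec, PMFProfile, block_analysis,
                  pmf_from_weighted_samples)
from .restraints import RestraintSpec

LN10 = float(np.log(10.0))


@dataclass
class RegionSpec:
    """Bound/unbound CV intervals (nm) along the PMF coordinate L."""

    bound: tuple = (0.0, 0.4)
    unbound: tuple = (2.0, 2.5)

    def __post_init__(self):
        if self.bound[1] <= self.bound[0] or self.unbound[1] <= self.unbound[0]:
            raise ValueError("regions must be non-empty intervals")
        if not (self.bound[1] <= self.unbound[0] or self.unbound[1] <= self.bound[0]):
            raise ValueError("bound and unbound regions must be disjoint")

    @property
    def l_u(self) -> float:
        """Length of the unbound interval, nm."""
        return float(self.unbound[1] - self.unbound[0])


@dataclass
class Constants:
    RT: float = RT_310
    V0: float = V0_STANDARD
    A: float = DEBYE_HUCKEL_A_310

    def __post_init__(self):
        if min(self.RT, self.V0, self.A) <= 0:
            raise ValueError("constants must be positive")


@dataclass
class ChargeSet:
    """Integer charges of cation, site and complex, plus ionic strength (M)."""

    z_cation: int = 2
    z_site: int = -2
    z_complex: int | None = None
    ionic_strength: float = 0.0

    def __post_init__(self):
        if self.z_complex is None:
            self.z_complex = self.z_cation + self.z_site
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")


@dataclass
class BindingFreeEnergyResult:
    dG_pmf: float
    dG_V: float
    dG_I: float
    dG0: float
    sem: float | None = None
    blocks: BlockAnalysisResult | None = None
    settings: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# the three terms

def _region_integral(pmf: PMFProfile, interval: tuple, RT: float) -> float:
    lo, hi = interval
    mask = (pmf.centers >= lo) & (pmf.centers <= hi) & np.isfinite(pmf.values)
    if mask.sum() < 2:
        raise ValueError(f"PMF has no support on region {interval}")
    x = pmf.centers[mask]
    y = np.exp(-pmf.values[mask] / RT)
    return float(np.trapezoid(y, x))


def delta_g_pmf(pmf: PMFProfile, regions: RegionSpec = RegionSpec(),
                RT: float = RT_310) -> float:
    """``RT ln( int_unbound e^{-PMF/RT} / int_bound e^{-PMF/RT} )``.

    Trapezoidal integration on the PMF grid; the PMF is expected to
    follow the unbound-mean-zero convention (any constant offset cancels
    in the ratio anyway).
    """
    zu = _region_integral(pmf, regions.unbound, RT)
    zb = _region_integral(pmf, regions.bound, RT)
    return float(RT * np.log(zu / zb))


def s_u_cross_section(R_cyl: float, K_res: float, RT: float = RT_310) -> float:
    """Effective cross-section (nm^2) of the flat-bottom cylinder.

    Closed form of ``int_0^inf 2 pi r exp(-U_res(r)/RT) dr`` for the
    flat-bottom radial wall:
    ``pi R^2 + 2 pi (sqrt(pi RT / (2 K)) R + RT/K)``.
    """
    if R_cyl < 0 or K_res <= 0:
        raise ValueError("require R_cyl >= 0 and K_res > 0")
    return float(np.pi * R_cyl**2
                 + 2 * np.pi * (np.sqrt(np.pi * RT / (2 * K_res)) * R_cyl
                                + RT / K_res))


def delta_g_volume(l_u: float, S_u: float, V0: float = V0_STANDARD,
                   RT: float = RT_310) -> float:
    """``-RT ln(l_u S_u / V0)``: sampled unbound volume vs standard state."""
    if min(l_u, S_u, V0) <= 0:
        raise ValueError("l_u, S_u and V0 must be positive")
    return float(-RT * np.log(l_u * S_u / V0))


def delta_g_ionic(charges: ChargeSet, A: float = DEBYE_HUCKEL_A_310,
                  RT: float = RT_310, literal: bool = False) -> float:
    """Ionic-strength correction to zero ionic strength.

    Under the limiting Debye-Hueckel law ``log10 gamma_i = -A z_i^2
    sqrt(I)`` the correction is
    ``dG_I = RT ln10 (-A sqrt(I)) (z_cation^2 + z_site^2 - z_complex^2)``.

    ``literal=True`` switches to the audit-only literal-ratio reading in
    which the activity "coefficients" themselves equal ``-A z_i^2
    sqrt(I)``; that expression is dimensionally unsound (coefficients go
    negative) and is provided purely for comparison.
    """
    z = charges
    sq = z.z_cation**2 + z.z_site**2 - z.z_complex**2
    root_i = np.sqrt(z.ionic_strength)
    if root_i == 0 or sq == 0:
        if not literal:
            return 0.0
    if literal:
        num = (-A * z.z_cation**2 * root_i) * (-A * z.z_site**2 * root_i)
        den = -A * z.z_complex**2 * root_i
        if num == 0 or den == 0:
            return 0.0
        return float(RT * np.log(num / den))
    return float(RT * LN10 * (-A * root_i) * sq)


# ----------------------------------------------------------------------
# assembly

def standard_binding_free_energy(pmf: PMFProfile,
                                 regions: RegionSpec = RegionSpec(),
                                 restraint: RestraintSpec | None = None,
                                 charges: ChargeSet | None = None,
                                 constants: Constants = Constants(),
                                 samples: np.ndarray | None = None,
                                 weights: np.ndarray | None = None,
                                 block_counts=None) -> BindingFreeEnergyResult:
    """Assemble ``dG0 = dG_PMF + dG_V + dG_I`` with a block-analysis SEM.

    When per-sample data are given (``samples``: retained 1D CV values,
    ``weights``: their reweighting weights), the SEM is estimated by
    recomputing dG0 on contiguous trajectory blocks and taking the value
    at the largest block size of ``block_counts`` (default 3..25).
    """
    restraint = restraint or RestraintSpec()
    charges = charges or ChargeSet()
    su = s_u_cross_section(restraint.R_cyl, restraint.K_res, constants.RT)
    dgv = delta_g_volume(regions.l_u, su, constants.V0, constants.RT)
    dgi = delta_g_ionic(charges, constants.A, constants.RT)
    dgp = delta_g_pmf(pmf, regions, constants.RT)
    dg0 = dgp + dgv + dgi

    sem = None
    blocks = None
    if samples is not None:
        if weights is None:
            weights = np.ones(len(samples))
        if block_counts is None:
            block_counts = range(3, 26)
        grid = GridSpec.uniform_1d(pmf.cv_name, float(pmf.centers[0]),
                                   float(pmf.centers[-1]), len(pmf.centers))
        records = np.column_stack([np.asarray(samples, float),
                                   np.asarray(weights, float)])

        def block_dg0(block):
            try:
                p = pmf_from_weighted_samples(block[:, 0], block[:, 1], grid,
                                              regions.unbound, constants.RT)
                return delta_g_pmf(p, regions, constants.RT) + dgv + dgi
            except ValueError:
                return np.nan  # block never visited a required window

        blocks = block_analysis(records, block_counts, functional=block_dg0)
        sem = blocks.plateau_sem

    return BindingFreeEnergyResult(
        dG_pmf=dgp, dG_V=dgv, dG_I=dgi, dG0=dg0, sem=sem, blocks=blocks,
        settings={"R_cyl": restraint.R_cyl, "K_res": restraint.K_res,
                  "l_u": regions.l_u, "bound": regions.bound,
                  "unbound": regions.unbound, "RT": constants.RT,
                  "V0": constants.V0, "A": constants.A,
                  "charges": (charges.z_cation, charges.z_site,
                              charges.z_complex),
                  "ionic_strength": charges.ionic_strength})


def delta_delta_g(result_a, result_b) -> tuple:
    """``ddG = dG0_a - dG0_b`` ("a versus b"); SEMs combine in quadrature.

    Accepts :class:`BindingFreeEnergyResult` objects or bare numbers
    (then the SEM is None).  Returns ``(ddG, sem)``.
    """
    ga, sa = _value_sem(result_a)
    gb, sb = _value_sem(result_b)
    sem = None if sa is None or sb is None else float(np.hypot(sa, sb))
    return float(ga - gb), sem


def fold_preference(dG0_a, dG0_b, RT: float = RT_310) -> tuple:
    """Fold-preference of the stronger binder (a) over b.

    ``fold = exp((dG0_b - dG0_a)/RT)`` with the convention that ``a`` is
    the stronger (more negative) binder; the uncertainty is propagated
    from the SEMs by quadrature: ``sigma_fold = fold * sqrt(sa^2+sb^2)/RT``.
    Returns ``(fold, sigma_fold)``.
    """
    ga, sa = _value_sem(dG0_a)
    gb, sb = _value_sem(dG0_b)
    fold = float(np.exp((gb - ga) / RT))
    sigma = None
    if sa is not None and sb is not None:
        sigma = float(fold * np.hypot(sa, sb) / RT)
    return fold, sigma


def _value_sem(x):
    if isinstance(x, BindingFreeEnergyResult):
        return x.dG0, x.sem
    if isinstance(x, (tuple, list)) and len(x) == 2:
        return float(x[0]), (None if x[1] is None else float(x[1]))
    return float(x), None
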