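# mgbind

Divalent cations such as Mg²⁺ can switch ion channels off by binding at
structural sites formed by pairs of acidic residues. Deciding whether a
candidate site in a cryo-EM structure is geometrically capable of
bridging a cation, and how strongly a cation binds there, requires a
chain of computations: geometric site scanning, enhanced-sampling
simulation along collective variables, free-energy-surface estimation,
minimum-free-energy-path extraction, and a standard binding free energy
with the proper reference-state corrections. `mgbind` implements that
chain as a tested Python library plus a set of analysis drivers, for
structural biologists and simulators who want each stage to be
verifiable against a brute-force ground truth at desk scale.

## What it computes

**Geometric site criterion.** A pair of acidic residues can coordinate a
divalent cation directly (not water-mediated) when their Cα atoms are
closer than a class-dependent cutoff: the sum of the Cα→carboxyl-carbon
offsets (0.25 nm for Asp, 0.35 nm for Glu) plus twice the
carboxyl-carbon–cation distance (2 × 0.3 nm), i.e. 1.1 / 1.2 / 1.3 nm
for DD / DE / EE pairs. Pairs sharing residues are merged into sites by
single linkage. `structure.py` also provides Cα distances, χ₁/χ₂
side-chain dihedrals, and a largest-empty-sphere pore-radius profiler.

**Toy sampling with known ground truth.** `landscapes.py` builds model
potentials — a particle in a flat-bottom cylinder (radius `R_cyl`, wall
constant `K_res`) attracted by one or two Gaussian "carboxyl" anchors,
optionally with an auxiliary hydration coordinate — whose free energy
surfaces are computable exactly by dense-grid quadrature. `sampling.py`
runs multiple-walker well-tempered metadynamics (overdamped Langevin;
bias factor γ = 5, hill height 0.3 RT, hill widths 0.05 nm for
distances and 0.1 for the hydration coordinate) and speaks the
PLUMED-dialect COLVAR/HILLS text formats.

**Free energy estimation.** `fes.py` reweights biased samples with
final-bias weights w ∝ exp(+V_b(s)/RT) onto CV grids, projects
surfaces, extracts 1D PMFs zeroed over an unbound window, and estimates
errors by block analysis. `mfep.py` finds minimum free energy paths on
2D surfaces with the zero-temperature string method.

**Standard binding free energy.** `binding.py` assembles

    ΔG⁰ = ΔG_PMF + ΔG_V + ΔG_I

with ΔG_PMF = RT ln(∫_unbound e^(−PMF/RT) / ∫_bound e^(−PMF/RT)),
ΔG_V = −RT ln(l_u·S_u / V⁰) where
S_u = πR_cyl² + 2π(√(πRT/2K_res)·R_cyl + RT/K_res) is the effective
cylinder cross-section and V⁰ = 1.661 nm³ the 1 M standard-state
volume, and ΔG_I the limiting Debye–Hückel correction to zero ionic
strength (RT = 2.577 kJ/mol throughout, i.e. 310 K). Derived
quantities: state differences ΔΔG⁰ and the fold preference
exp(ΔΔG⁰/RT) between two cations.

## Worked example

The numbered drivers under `analysis/` run the study end to end and
write tables under `results/`:

```bash
python analysis/01_scan_sites.py
# closed-state geometry: 4 DD sites (one per chain), Calpha distance 1.05 nm < 1.1 nm cutoff
# open-state geometry:  0 sites -- the 0.20 nm pair expansion abolishes every site

python analysis/03_sample_and_estimate.py 1
# dG0 = -0.62 +/- 0.17 kJ/mol (dG_PMF -1.27, dG_V +0.65, dG_I +0.00)
# quadrature ground truth -0.52 kJ/mol -> recovery error -0.10 kJ/mol
# MFEP barrier along the binding path: 6.7 kJ/mol (converged=False)

python analysis/04_selectivity.py
# Mg2+ over Ca2+ fold preference: 35.5 +/- 9.9 (~35)
# site expansion: ddG0 = +3.5 +/- 0.6 kJ/mol (Mg2+), -1.1 +/- 0.7 kJ/mol (Ca2+)
```

Reading the numbers: the site scanner finds one two-aspartate site per
chain in the closed-like tetramer and none after the 0.2 nm expansion
that mimics the helix rotation of channel opening. The toy
metadynamics run recovers the quadrature ground-truth ΔG⁰ of the
shipped binding landscape to 0.1 kJ/mol, with the block-analysis SEM as
the error bar. The selectivity arithmetic turns the reported per-state
ΔG⁰ values into the ~35-fold Mg²⁺-over-Ca²⁺ preference and the ±ΔΔG⁰
shifts caused by the 0.1 nm site expansion. A `mgbind` console command
exposes the same stages as subcommands (`simulate`, `fes`, `mfep`,
`dg0`, `scan-sites`, `pore`, `compare-states`, `demo`).

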