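# Methods

This note documents the models, estimators, parameter choices and
numerical conventions behind `mgbind`, and what the synthetic systems do
and do not establish about real atomistic calculations.

## Geometric site criterion

A divalent cation bridging two carboxylates directly requires the two
Cα atoms to lie within the sum of each residue's Cα→carboxyl-carbon
offset (0.25 nm Asp, 0.35 nm Glu) and twice the carboxyl-carbon–cation
contact distance (0.3 nm each): 1.1, 1.2 and 1.3 nm for DD, DE and EE
pairs. The inequality is strict — a pair exactly at the cutoff is
rejected — and candidate pairs sharing a residue are merged into sites
by single linkage, so a chain of pairwise contacts becomes one
multi-residue site. Both intra- and inter-chain pairs are scanned and
reported with chain labels, since geometry alone cannot say which the
original survey considered. The "intracellular side" restriction is a
user-supplied axial slab: no membrane detection is attempted because no
quantitative boundary is defined anywhere we could adopt one from.
Density-based filtering (checking for experimental map support at a
candidate site) is out of scope: it is not computable from coordinates.

Side-chain dihedrals use the IUPAC sign convention (χ₁ = N-Cα-Cβ-Cγ;
χ₂ = Cα-Cβ-Cγ-O_D1 for Asp, -C_D for Glu), computed with the
praxeolitic dihedral formula; a right-handed rotation of the distal
atom about the Cα→Cβ axis increases χ₁.

The pore profiler is a plane-wise largest-empty-sphere search: at each
axial slice the pore radius is max over in-plane centres of
min_i(|x − atom_i| − vdW_i), located by Nelder–Mead from thirteen
starts on and around the axis, clipped at zero and capped by a declared
sentinel radius (default 1.5 nm) for empty slices. Default vdW radii:
C 1.7, N 1.55, O 1.52, S 1.8 Å (table overridable). This is a
deliberately simple profiler: it reports the same qualitative
constriction structure as dedicated pore-tracing tools but does not
trace a connected channel centreline.

## Toy landscapes and their ground truth

The synthetic systems stand in for cation-binding simulation boxes: a
single particle ("the cation") inside a flat-bottom cylinder (radius
R_cyl, wall constant K_res = 10⁵ kJ mol⁻¹ nm⁻²) attracted by one or
two fixed isotropic Gaussian wells ("carboxyl anchors", separation
0.3 nm in the two-anchor preset, mirroring two carboxyl carbons
bridged by one cation), plus an (r_rep/r)¹² soft-core repulsion.
Because the real simulation box bounds the axial coordinate, the
restraint optionally carries flat-bottom axial caps with the same wall
constant; the shipped binding landscape uses R_cyl = 0.9 nm and caps
at (−0.3, 2.7) nm. An optional auxiliary scalar h emulates the water
coordination number of the cation: it is harmonically tethered
(k_h = 20 kJ/mol per unit²) to a rest value that relaxes from 6 in
bulk toward ~4 at the site as the anchors' Gaussian envelopes overlap
the particle — enough to exercise three-CV machinery (L₁, L₂, CN_W)
without any explicit solvent. Charge-scaling factors used in
electronic-continuum-corrected force fields (0.8/0.85) have no role in
this toy model and are treated as metadata only.

Every landscape is integrable by brute force: the reference FES is
F(s) = −RT ln ∫ δ(CV(x)−s) e^(−U(x)/RT) dx evaluated by
Boltzmann-weighting a dense configuration lattice (default spacing
0.02 nm) and histogramming the CV values; the minimum is shifted to
zero and a provenance warning records spacings too coarse for the well
widths. Counting lattice points in thin curved CV shells carries a few
per cent noise; basin free-energy differences (integrated quantities)
converge to < 0.05 kJ/mol under spacing refinement on the shipped
fixtures. The 1D double-well preset (minima at 0.25/2.25 nm, width
0.15 nm) includes a variant whose deep-well depth
(15.929 454 586 553 07 kJ/mol) was frozen once by root-finding so the
basin free-energy gap is exactly 5.0 kJ/mol at RT = 2.577.

Toy tetramers are built from internal coordinates (NeRF placement of
backbone + Cβ/Cγ stubs and carboxyl oxygens) with exact prescribed
Cα–Cα pair distances and C_n rotational symmetry; they round-trip
through PDB at 10⁻³ Å.

## Sampler

The integrator is Euler–Maruyama overdamped Langevin,
x' = x − (Δt/γ_f)∇(U + V_b) + √(2RTΔt/γ_f)·ξ, with toy-scale Δt and
friction γ_f — the estimators downstream, not the integrator, are the
substance here, so no atomistic machinery (constraints, PME, NPT) is
emulated. Two numerical guards matter:

- **Drift cap.** The deterministic displacement per step is capped
  (default 0.02 nm). The 10⁵ kJ mol⁻¹ nm⁻² walls are orders of
  magnitude too stiff for explicit integration at any useful Δt; the
  cap turns them into effectively hard walls while leaving the
  interior dynamics untouched. The resulting wall-layer density error
  shifts volume-type terms by < 0.05 kJ/mol — far below the sampling
  error at desk scale.
- **Well stiffness vs timestep.** Euler sampling inflates the variance
  of a harmonic basin by ≈ 1/(1 − kΔt/2γ_f); presets keep
  kΔt/γ_f ≲ 0.2 so the discretisation bias stays well below the
  statistical error.

Well-tempered metadynamics deposits Gaussian hills every
`deposit_stride` steps with height h = h₀·exp(−V_b(s)/((γ−1)RT)),
γ = 5 and h₀ = 0.3 RT by default, hill widths 0.05 nm (distances) and
0.1 (hydration coordinate). All walkers share one bias and deposit in
a fixed round-robin order each deposition step (the synchronisation
convention is ours; nothing mandates another). Runs are bit-for-bit
reproducible given (seed, walker count, strides); changing only the
walker count changes trajectories by construction.

Hills are summed exactly on demand, or accumulated on a resolved CV
grid ("grid cache") with multilinear interpolation for speed; the cache
is an approximation (observed ≤ 0.05 kJ/mol against exact summation on
the shipped fixtures) and the exact path remains available
(`BiasState.exact_bias`) and is what the tests compare against.
COLVAR/HILLS files use the PLUMED text dialect (`#! FIELDS ...`);
replaying bundled records through the same grid cache reproduces a live
run's FES to output precision.

Desk-scale run lengths were chosen so that recovery errors sit
comfortably inside the test tolerances across seeds: 16 walkers ×
400 000 steps for the 1D double well (≈ 1 min on one CPU) and 16 ×
300 000 for the 3D binding landscape (≈ 1.5 min).

## Free energy estimation

Reweighting uses the final-bias convention: after discarding a burn-in
(defaults mirror the source trajectories' fractions — one third for
the acetate-like 1D fixture, one quarter for the protein-like binding
landscape), each sample is weighted by w ∝ exp(+V_b_final(s_t)/RT) and
histogrammed. The cited reweighting literature admits several
estimators; the final-bias choice is declared rather than inferred,
and a time-dependent estimator is an extension hook. Consequences kept
as invariants: an identically-zero bias reduces to the plain histogram
exactly; adding any constant to the bias leaves the FES unchanged;
histogram bins are half-open [lo, hi) with the global top edge closed;
unvisited cells are NaN, excluded from projections and never imputed.
Projections are Boltzmann sums F_proj = −RT ln Σ e^(−F/RT) re-zeroed
to minimum 0; PMFs are 1D projections shifted so the mean over the
unbound window is zero.

Block analysis splits the retained series into k contiguous equal
blocks (k from 3 to 100 for the 1D fixture, to 25 for the binding
landscape, truncating remainders), applies the functional per block and
reports mean ± SEM per k. The quoted value and SEM are those at the
largest block size — the smallest usable k — matching the convention of
taking the plateau from the large-block end; blocks whose functional is
undefined (e.g. a block that never visits the unbound window) are
dropped from that count.

## Minimum free energy paths

The zero-temperature string method: n_nodes (default 100) between
fixed endpoints, each iteration moving interior nodes down the
bilinearly interpolated FES gradient (central differences on the grid)
and reparameterising to equal arclength, until the maximum displacement
drops below tol (default 10⁻⁴ CV units). Unvisited cells are filled
with a high artificial wall for interpolation; per-iteration moves are
capped at half a grid cell so the wall cannot catapult nodes. If the
straight initial path crosses missing cells, a uniform-cost search over
finite cells seeds the string. On statistically rough reweighted
surfaces the string reaches a jitter floor set by gradient noise and
may report `converged=False` at tight tolerances; the barrier estimate
is stable well before that. No climbing-image or finite-temperature
refinement is attempted.

## Standard binding free energy

ΔG⁰ = ΔG_PMF + ΔG_V + ΔG_I, an exact identity of the returned record.
ΔG_PMF integrates e^(−PMF/RT) by trapezoid over the bound (default
L < 0.4 nm) and unbound (2.0–2.5 nm, l_u = 0.5 nm) windows, endpoints
included. ΔG_V = −RT ln(l_u·S_u/V⁰) with
S_u = πR² + 2π(√(πRT/2K)·R + RT/K), verified against its defining
radial integral to four significant figures across R ∈ [0, 2] nm,
K ∈ [10³, 10⁷]. For the ionic term, the printed source expression sets
the activity coefficient itself to −A z²√I, which cannot be a
coefficient (it is negative and dimensionally unsound); we implement
the limiting Debye–Hückel law log₁₀γᵢ = −A zᵢ²√I, giving
ΔG_I = RT·ln10·(−A√I)(z_cation² + z_site² − z_complex²) with
A = 0.519 M^(−1/2) at 310 K. A `literal=True` switch reproduces the
literal reading for audit only. The 1D PMF coordinate for the
two-distance site is configurable (L₁ by default) since the choice is
not determined by the definitions. ΔΔG⁰ follows the "a versus b"
convention (ΔG⁰_a − ΔG⁰_b) and fold preference is exp((ΔG⁰_b −
ΔG⁰_a)/RT) with a the stronger binder; uncertainties combine in
quadrature, which assumes independent errors between states.

## What the toy results do and do not show

Passing tests establish that the estimator chain — sampling, bias
bookkeeping, reweighting, projection, path finding, ΔG⁰ assembly and
its corrections — is internally correct against brute-force oracles on
landscapes with known answers, at desk scale and fixed seeds. They say
nothing about force-field accuracy, explicit-solvent effects, charge
scaling, or the magnitude of any real system's binding energies: the
published atomistic ΔG⁰ values require microsecond-scale simulations
and are reproduced here only at the level of the arithmetic that
combines them (state differences and fold preferences). The toy
hydration coordinate is a caricature of a water coordination number:
it exercises the CV plumbing, not hydration physics.

## Known limitations

- Final-bias reweighting on a still-evolving bias carries a small
  systematic component that decays with run length; at the shipped run
  lengths it is below the block-analysis SEM.
- The pore profiler optimises per-plane and can jump between disjoint
  cavities in pathological geometries; multi-start from the axis makes
  this unlikely for channel-like inputs.
- The quadrature reference inherits lattice-counting noise in thin CV
  shells (a few per cent per bin); integrated basin quantities are far
  more accurate than per-bin values.
- Single-linkage site merging can chain residues into one large site
  through marginal contacts; the unmerged pair list is always
  available.
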