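# Methods

This note records the models implemented in `cdscs`, the choices made where
the design was open, and what the tests do and do not establish.

## Electronic-structure engine

**Scope.** Restricted closed-shell singlets only.  Supported elements/bases:
H, He, Li, O in STO-3G; H, He in cc-pVDZ and cc-pVTZ.  This covers the
motivating systems (H₂, He, He₂, LiH, H₂O); open-shell species enter the
benchmark machinery only through precomputed species records.

**Integrals.** McMurchie–Davidson over contracted Cartesian Gaussians up to
d functions, with the Boys function from a convergent series (x < 35, with
downward recursion) and the standard asymptotic form beyond.  Cartesians are
transformed to real solid harmonics and contracted AOs renormalized to unit
self-overlap; all post-HF results are invariant to that normalization.
Basis exponents and STO-3G contractions are the published parameter tables;
correlation-consistent s contractions are generated at build time by their
defining construction — the atomic HF orbital in the uncontracted primitive
set (exact for hydrogen; a closed-form one-center SCF for helium).  The
generated coefficients reproduce the published tables to their printed
precision, which doubles as a validation of the one-center integral code.

**SCF.** DIIS-accelerated RHF; defaults 1e-9 hartree on the energy and 1e-7
on the density, chosen so that quantities printed to 3 decimals in au carry
no convergence noise.

**MP2.** Canonical spatial-orbital amplitudes
`t_ij^ab = (ia|jb)/(ε_i+ε_j−ε_a−ε_b)`;
`E_OS = Σ t (ia|jb)`, `E_SS = Σ (t − t(ab↔ba)) (ia|jb)`, both ≤ 0, summing
to the MP2 correlation energy.  All-electron by default; `frozen_core=True`
drops one core pair per non-H/He atom from the amplitude space.  Published
benchmark components rarely state their core treatment, so both options are
exposed and every record carries the flag.

**Unrelaxed density.** HF density plus the amplitude-quadratic oo and vv
blocks; its per-spin eigenvalues lie in [0, 1] by construction and are
clamped within 1e-8 (beyond raises).  These natural occupancies are the sole
input to the correlation indices — the unrelaxed choice keeps occupancies in
[0, 1] and costs nothing beyond the amplitudes.

**Relaxed densities.** The gradient-theory response densities: the ov block
solves the closed-shell Z-vector (CPHF) equations with the singlet orbital
Hessian; the two-particle density is a separable part, linear in the
relaxed one-particle correction, plus the amplitude cumulant (OS block:
plain amplitudes; SS block: antisymmetrized; each entering twice, once per
first-order bra/ket).  Two identities pin the construction and are enforced
in tests: `tr(hD) + ½Γ·g + E_nuc = E_HF + E_MP2` exactly, and agreement of
`tr(D w)` / `Vee[Γ]` with finite-field derivatives of the total MP2 energy
under one-electron and ERI-scaling perturbations (Hellmann–Feynman for the
Lagrangian).  Relaxed densities are implemented for the all-electron case.

*Known property:* response densities are not N-representable.  They satisfy
the opposite-spin contraction and pair count exactly, but the same-spin
channel carries an intrinsic pair-count offset equal to −tr of the oo
occupancy correction (≈ +0.01 pairs for H₂/cc-pVTZ).  Contraction sum rules
are therefore asserted exactly for HF/FCI densities and only loosely for
relaxed MP2; the hole-integral sum rule `∫h = 0` is exact for FCI−HF and
approximate for MP2−HF.

**FCI.** Determinant CI restricted to ≤ 4 electrons.  Two-electron singlets
use a dense spatial pair-basis Hamiltonian; the general case uses
string-replacement lists with a Davidson-type iterative ground state (dense
diagonalization under 600 determinants).  Spin-blocked two-particle
densities are assembled from single-replacement operator actions, and the
pair-count/contraction sum rules are exact.

## Coulomb holes and intracules

`ΔVee = Vee(correlated) − Vee(HF)` is computed *algebraically* from the
two-particle densities and MO repulsion integrals — this is the quantity
reported by the acceptance script and it carries no grid error.  The radial
intracule `I(r₁₂)` is computed by direct two-point quadrature over
Becke-partitioned atom-centered grids (Murray–Handy–Laming radial map,
Gauss–Legendre × uniform-φ angular shells) with `‖r₁−r₂‖` resolved by
binning (default 0–15 bohr, 0.05-bohr bins).  This replaces the analytic
intracule technology used in the original analysis; accuracy is certified by
sum rules rather than assumed:

* pair count vs the density's own algebraic pair count — defect ~1e-6 at the
  default 35×10×20 grid (tolerance 1e-2, failing loudly above it);
* `∫ I/r₁₂` vs algebraic Vee — the 1/r₁₂ weight converges more slowly under
  two-point quadrature (~3e-3 au at default, 1e-3 au at a 45×12×24 grid);
  the per-pair contribution is accumulated with exact distances, so binning
  adds no extra error to this check;
* radial refinement monotonically reduces the normalization defect.

The long-range dispersion discussion is supported only as a short/long-range
split of the 1/r₁₂-weighted hole at a configurable cutoff; no cumulant
partition of the hole is implemented.

**Geometries.** "Equilibrium" is rarely pinned to a number in hole
analyses; fixtures use experimental bond lengths (H₂ 0.7414 Å, LiH 1.5957 Å and twice
that for the stretched case, He₂ 2.97 Å near the dispersion minimum), all
overridable via XYZ input.  The headline H₂ numbers are insensitive to the
re choice at the ±0.002 au level.

## Correlation indices

`I_ND`, `I_D`, `I_T` as in the module docstring; `I_D ≥ 0` holds analytically
(½√x ≥ x on [0, ¼]).  Conventions chosen here:

* `N` is the full electron count including core, matching the all-electron
  default; frozen-core amplitude sets still use the full spectrum.
* `I_T < 1e-12` (idempotent density) is treated as the purely dynamic limit
  `r_D = 1`, `r_ND = 0` — an uncorrelated-reference molecule should scale
  like a dynamically correlated one.
* `I_ND^max` is defined as the largest single-orbital term `max n(1−n)`,
  un-normalized; the 0.030 screen then corresponds to occupancies of about
  0.969/0.031.  Normalization conventions for this diagnostic vary in the
  literature, so the choice is isolated in one place (the
  `CorrelationIndices.i_nd_max` producer) for easy replacement.

## Scaling model

`c_SS = a·r_ND + b`, `c_OS = a′·r_D + b′`, evaluated per species and
combined by stoichiometry; coefficients are never clipped — the published
interval [0.79, 1.21] for the four-parameter model is emergent.  The published
descriptions of the two-parameter model are internally inconsistent about
which coefficient multiplies which ratio; the assignment
`c_OS = 1.38·r_D`, `c_SS = 2.89·r_ND` is adopted as the only one consistent
with the reported c_OS range on the training set, and the preset is a single
registry entry should the convention need swapping.

Error surfaces over a uniform (c_OS, c_SS) grid are affine in the two
coefficients per reaction, so the exact-zero locus is a straight line of
slope `−(Σν E_OS)/(Σν E_SS)`; tests verify the grid against this closed
form.

## Benchmark statistics

Signed error = computed − reference (kcal/mol; 627.509474 kcal/mol per
hartree).  WTMAD2 uses the configurable constant 56.84 kcal/mol; per-subset
`|ΔE|avg` is computed from the loaded reference energies by default (so
down-sampled sets get their own weights), with published full-set averages
accepted as overrides.  The multireference screen drops any reaction
containing a species with `I_ND^max` above the threshold (per-species rule;
whether the original analysis screened whole "systems" or individual species
is ambiguous in the published protocol).  Subset groupings (e.g. "everything but noncovalent sets")
are named collections in the data file, not code.

## Parameter fitting

Each reaction error is affine in (a, a′, b, b′), so MAD minimization is a
convex least-absolute-deviations problem.  Primary solver: exact LP
reformulation (slack variable per reaction, HiGHS); optional cross-check: a
Nelder–Mead multistart that must agree to 1e-4 kcal/mol.  Initial point for
reporting purposes is canonical MP2 (a = a′ = 0, b = b′ = 1).  Degenerate
training sets are detected by SVD of the design matrix and reported as
explicit null directions (warning plus result field), never silently
resolved.  WTMAD2 is deliberately not offered as a training objective; the
training protocol minimizes plain unweighted MAD (reactions weighted
equally).  An RMSD objective is available and reduces to least squares.

## Synthetic data

The generator's defaults are the package's standing study conditions:
40 species, `r_D ∈ [0.55, 0.99]` (the range typical of single-reference
thermochemistry sets), `E_HF ∈ [−120, −20]`, `E_OS ∈ [−1.2, −0.2]`,
`E_SS ∈ [−0.45, −0.05]` hartree, reference noise σ = 1 kcal/mol, fixed seed.
Spectra come from the two-pair family described in the module docstring,
with a closed-shell core of 3 orbitals per spin (N = 10).  What this
emulates: the algebraic structure linking indices, components and reaction
energies, with realistic magnitudes.  What it does not: real electronic
structure (no basis-set or geometry dependence, no correlated noise between
species sharing atoms, no heavy-tailed reference errors).  Passing tests
therefore establish the statistics/fitting machinery and the index algebra,
not chemical accuracy on real benchmark sets — the latter is represented by
the desk-scale H₂/He/He₂ calculations.

## Problem sizes and determinism

Default test and acceptance runs use H₂/He/He₂ in STO-3G–cc-pVTZ (≤ 28
basis functions), FCI spaces ≤ ~2000 determinants, intracule grids of a few
thousand points, and synthetic sets of ≤ 300 reactions — all chosen as
comfortable single-core sizes.  Every stochastic component (synthetic
generator, property tests) is seeded; the acceptance quantities themselves
are deterministic.

## Known limitations

* No open-shell reference, no ECPs, no diffuse-function augmentation
  recipes, no analytic gradients.
* Relaxed densities all-electron only.
* FCI capped at 4 electrons (by design, for exact hole references).
* Intracule `∫I/r₁₂` agreement limited by two-point quadrature of the
  Coulomb cusp (see tolerances above); `ΔVee` itself is exact.
* cc-pVDZ/TZ parameters are included for H and He only; LiH analysis beyond
  STO-3G needs externally supplied records.
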