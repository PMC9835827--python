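# Methods

## Model and assumptions

`pmmkit` treats a molecular system as a rigid quantum center (QC) embedded
in a classical point-charge environment sampled by MD. The QC's electronic
structure is represented on a truncated basis of its gas-phase eigenstates
Φ⁰_l (energies ε⁰_l, electric-dipole matrix ⟨Φ⁰_l|μ̂|Φ⁰_l'⟩), computed once
by an external quantum-chemistry program. Per frame, the environment enters
only through its electrostatics: the potential V and field E it exerts at
the QC. Key assumptions:

* **Rigid QC.** One reference geometry is superimposed on every frame;
  intramolecular QC motion is not part of the electronic model (flexible
  fragments belong in the classical region).
* **Electrostatic-only coupling.** Exchange, dispersion and polarization
  feedback from QC to environment are not modeled.
* **Truncated multipole expansion.** The QC-based Hamiltonian keeps the
  monopole (q_T·V(r₀)) and dipole (−E·μ) terms about the QC center of
  mass. The atom-based variant rebuilds only the *diagonal* from per-state
  atomic charges times per-nucleus potentials, Σ_N q_N^l V(R_N): atomic
  dipoles are neglected (each state's density is taken as symmetric about
  its nucleus within its atomic region), and off-diagonal atomic operators
  — not available from standard population analyses — keep the dipolar
  form. Higher multipoles are out of scope.
* **Vertical transitions.** Spectra use fixed-nuclei excitation energies;
  vibronic structure is not resolved.
* **Classical nuclei in the free-energy cycle.** Quantum vibrational
  contributions to reaction free energies are disregarded; the ionic
  relaxation terms of the two reaction directions are assumed to cancel,
  which is what licenses combining forward and reverse exponential
  averages as their arithmetic mean.

## Coordinate handling

Everything downstream of I/O is in Hartree atomic units; converters exist
only at file boundaries (`units.py`, with the angstrom/bohr factor pinned
to 0.529177210903 so file round-trips are independent of the installed
scipy's CODATA revision).

The QC reference geometry is mapped onto each frame by a mass-weighted
Kabsch superposition (proper rotation only: the determinant branch is
forced to +1, so a mirror-image frame yields the best proper rotation and
a nonzero RMSD rather than a reflection). The expansion origin r₀ is the
mass-weighted center of the fitted QC. The lab-frame field at r₀ is rotated
*back* into the QC reference frame before contracting with the dipole
matrix — equivalent to rotating the dipoles lab-ward, but it keeps the QC
properties frame-fixed. A single-atom QC has no orientation: the fit is
skipped, the frames are taken as parallel, and r₀ is the atom position.
Two-atom or collinear QCs are rejected as rotationally underdetermined.

Periodic boundaries: when the trajectory carries a box, displacement
vectors from the evaluation point to each environment charge are reduced by
the minimum-image convention in fractional coordinates (triclinic-safe), so
a charge and its image are never both counted. The Coulomb sums are exact
over all environment atoms — no cutoff by default; a charge closer than
1e-6 bohr to an evaluation point is a hard error (a clash, not a number).

## Numerical choices

* **Diagonalization** uses `numpy.linalg.eigh` on the symmetrized matrix;
  asymmetry above 1e-8 is an input error. Eigenvalues ascend.
* **Eigenvector sign/continuity.** Signs are not physical; to make
  coefficient trajectories plottable the first frame fixes each column's
  largest-magnitude coefficient positive, and every later frame flips
  columns so their overlap with the previous frame's same-index column is
  non-negative. Degenerate eigenvalues (within 1e-10 relative) are
  best-effort reordered inside their group by greedy maximal |overlap|
  with the previous frame before the sign pass.
* **Binning** for spectra uses half-open intervals [left, right): a
  frequency exactly on an edge belongs to the bin on its right. Defaults:
  bin width 0.002 eV (fine enough that binning error is invisible at the
  default broadening), σ = 0.034 eV (a width that has served well for
  small and medium organic chromophores; it is a user parameter, not
  estimated from the data). The frequency grid spacing tracks σ (≤ σ/4) so
  narrow lineshapes are resolved.
* **Extinction prefactor.** The molar extinction is assembled as
  ε(ν) = K·ν·Σ_bins (n/N)·|μ|²·ρ(ν; ν_ref, σ) with
  K = 2π²N_A/(3 ln10 ε₀ h c) in M⁻¹ cm⁻¹ after unit conversion — the
  standard cross-section/oscillator-strength relation for an ensemble with
  a unit-normalized lineshape. ν·ρ(ν) is invariant under the eV↔Hz change
  of variable, so the eV grid feeds the SI prefactor directly.
* **Exponential averages** are evaluated with max-shifted log-sum-exp
  accumulation, finite for |βΔU| up to ~1e4. The gap convention is fixed
  as ΔU = U_P − U_R in *both* ensembles; the estimator direction is keyed
  to the ensemble (forward on R, reverse on P), never to re-signed data —
  the classic source of sign errors in this family of estimators.
* **Uncertainty.** The reported standard error is a block bootstrap
  (default 50 contiguous blocks per ensemble, 1000 resamples, seeded),
  chosen to respect serial correlation within blocks; it is this package's
  own estimator, not a standard attached to the method.
* **Gas-phase offset.** When R- and P-species energy files are on
  different (relative) scales, the reconciling offset is an explicit user
  input in hartree; it is never inferred, because silently aligning
  absolute scales from relative files would be unsafe.

## Synthetic data and what the tests show

The fixtures module generates the study systems used throughout the tests
and the acceptance script:

* a **two-state QC** (gap 0.1 hartree, unit transition dipole) next to a
  single point charge whose distance jitters around 4 bohr — chosen so the
  dipolar coupling (~0.03 hartree at closest approach) visibly mixes the
  states without inverting them;
* **random-field runs**: a multi-state QC with a random symmetric dipole
  matrix and one charge at a random direction each frame, exercising the
  full fit→field→build→diagonalize loop with non-trivial mixing;
* **Gaussian energy gaps** with means −500 and −510 kJ/mol and common
  σ = 5 kJ/mol at 300 K — a linear-response-consistent pair whose combined
  free energy has the closed form (μ_R + μ_P)/2.

Trajectory files are multi-MODEL PDB; written coordinates are quantized to
the PDB/float32 precision the reader yields, so closed-form oracles and the
file-reading pipeline see bit-identical geometry and can be compared at
1e-12.

These fixtures deliberately do **not** emulate real solvated systems: there
is no solvent structure, no charge anticorrelation, no conformational
dynamics, and trajectories are hundreds of frames rather than the 10⁴–10⁵
a production study would use. Passing tests therefore demonstrate the
correctness of the electrostatics, the matrix construction, the estimators
and the bookkeeping — not the physical accuracy of any particular QC
parameterization. Problem sizes in the default test run (≤1000 frames,
≤5 states, N = 10⁵ gap samples) are the package's chosen desk-scale
conditions.

## Known limitations

* No polarizable environment; the perturbation is one-way.
* The atom-based expansion needs per-state atomic charges from the user's
  quantum-chemistry workflow; charge sets that do not sum to the QC total
  charge (default tolerance 1e-3 e) are rejected rather than renormalized.
* State tracking across frames is by energy order plus overlap continuity;
  genuine conical-intersection passages can still relabel states, and no
  automatic crossing detection is attempted.
* The free-energy module assumes the two input eigenvalue trajectories are
  frame-aligned over the same ensemble; it checks counts, not timestamps.
* Refractive-index/local-field corrections to the extinction coefficient
  are not applied.
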