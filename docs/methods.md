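# Methods

## The problem

Electrostatic-embedding QM/MM calculations let the classical environment
polarize the quantum region by adding the potential of every MM point charge
to the one-electron Hamiltonian.  The cost of the required three-center
integrals grows linearly with the number of MM charges, which is wasteful
for the tens of thousands of distant charges in a solvated or protein
environment whose individual influence on the QM density is tiny but whose
collective contribution is not (around an anion it can reach tens to
hundreds of kcal/mol).  This package implements and benchmarks a hybrid
treatment for non-periodic calculations: charges near the QM region interact
with the explicit electron density, while the far field interacts with a
compact multipolar representation of the QM subsystem, the two regimes
joined smoothly by a switching function at a distance cutoff.

## Energy models

Let the QM region carry nuclei Z_A at r_A and density rho(r), and the
environment carry point charges q_B at r_B.

* **Reference (all-charge density embedding).**
  E = sum_A Z_A phi(r_A) − ∫ rho(r) phi(r) dr with
  phi(r) = sum_B q_B / |r − r_B|.  Everything else is measured against this.
* **Mechanical.**  Fixed force-field charges q_A^ref on QM atoms:
  E = sum_AB q_A^ref q_B / r_AB.
* **Multipolar.**  Per-site generalized moments M_A^m (charge, Cartesian
  dipole) contracted with the local Taylor expansion of the MM potential,
  E = sum_Am M_A^m F_A^m, where F_A^0 is the MM potential at the site and
  F_A^{1..3} the electric-field components, built from the charge/dipole
  interaction tensor T (1/r and (r_A−r_B)/r³ kernels).
* **Mulliken moments (MulC/MulCD).**  The density matrix is partitioned by
  basis-function ownership (gross populations, symmetrized density matrix);
  q_A = Z_A − ∫rho_A and the site dipole is the electron-density moment
  ∫(r−r_A) rho_A.
* **ESP moments (ESPC/ESPCD).**  Moments least-squares fitted (SVD
  pseudo-inverse) to the molecular ESP on layered van-der-Waals surface
  grids.  The fitted problem K^T M = phi_s admits an exact dual: projecting
  the far-field MM charges onto the grid, q_s = sum_Am F_Am (K^−1)_Am,s,
  reproduces the multipolar energy identically as sum_s q_s phi_s.  This
  identity is the module's master oracle and also the route by which the
  far field enters the SCF: the grid charges are fixed by the MM geometry,
  density-independent, and therefore variationally exact as ordinary
  external point charges.
* **Truncation / MMLC.**  Far field dropped entirely, or restored
  classically with force-field charges on the QM atoms.

### Dipole sign convention

The stored site dipole is the *positive electron-density* moment
mu_A = +∫(r−r_A) rho_A(r) dr, i.e. the negative of the physical fragment
dipole.  With F^{1..3} equal to the electric field (−∇phi) and the energy
written as sum M F, this is the unique convention under which the
multipolar energy converges to the exact density–charge Coulomb energy in
the far-field limit; the far-field convergence-order tests pin it down
numerically (charges-only error ~ d^−2, charges+dipoles ~ d^−3).

## Cutoffs and switching

The distance of an MM charge to its *closest* QM atom decides near vs far.
Atom-based cutoffs are used with the smooth schemes; group-based cutoffs
(a whole water/residue moves together, any-member-inside rule) with the
discontinuous Step scheme, so the near field never acquires an artificial
net charge from a split molecule.  The boundary r = r_off belongs to the
near field.

Near-field charges are split exactly into a density-embedded portion
S(r) q and a multipole-side complement (1 − S(r)) q.  Four schemes are
implemented (u = r/r_off, all 0 beyond r_off):

* Step: 1
* Shift: (1 − u²)²
* Switch: 1 below r_on (default 0.75 r_off), then
  (r_off²−r²)² (r_off²+2r²−3 r_on²)/(r_off²−r_on²)³
* LREC: 1 − (2(1−u)³ − 3(1−u)² + 1)²

Shift/Switch/LREC are continuous with zero slope at r_off (Switch also at
r_on); conservation q_I + q_II = q holds exactly because the complement is
computed by subtraction.  Distances are never minimum-imaged: the method is
deliberately non-periodic.

## Benchmark protocol

Per configuration: (1) converge the SCF with all charges embedded (the
reference); (2) evaluate each model's hybrid electrostatic energy with the
*reference* density; (3) re-converge the SCF under the model's embedding
operator starting from the reference orbitals — the polarization energy is
the first-minus-last cycle difference (non-positive, by the variational
principle), and its deviation from the reference row (identically zero)
measures how far the operator distorts the wavefunction; (4) compare
Mulliken and ESP charges and the lowest CIS excitation of the relaxed
density against the reference ones.  RMSDs are taken over configurations
(charges pooled over atoms as well).

The Mulliken long-range term is linear in the density matrix, so its SCF
operator is a constant one-electron matrix plus a nuclear shift — no
response kernel exists, and the same argument lets static external charges
carry the ESP term.  Embedding enters the excited-state calculation only
through the ground-state Hamiltonian.

## Synthetic solvation boxes

Configurations come from a seeded generator, not from MD: rigid three-site
waters with the TIP3P geometry (r_OH = 0.9572 Å, 104.52°) and charges
(−0.834/+0.417 e), placed uniformly in a cube around the solute with an
O-solute exclusion of 2.6 Å and an O–O floor of 2.5 Å, uniformly random
orientations.  The optional anion bias rotates a water so one O–H bond
points at the nearest solute atom with probability
exp(−(d − 2.6 Å)/3 Å), a cartoon of the hydrogen-toward-anion ordering of
a real first solvation shell; it reproduces the qualitative diagnostics of
real solvated anions (positive scaled near-field net charge under LREC,
site potentials better reproduced by scaled truncation than plain
truncation).  What the generator does **not** emulate: liquid-state
density and structure (the default 200 waters in a 30 Å box are dilute),
water–water correlation beyond steric exclusion, counter-ions, and
conformational motion of the solute.  Passing benchmarks therefore
demonstrate correctness and convergence behaviour of the embedding
machinery on realistic charge layouts, not force-field-quality solvation
thermodynamics.

## Numerical choices

* Internal arithmetic in Hartree atomic units; lengths at the interface in
  Å, energies in kcal/mol (1 bohr = 0.529177210903 Å, 1 hartree =
  627.509474 kcal/mol, defined once in `system_io`).
* ESP grids: Fibonacci-lattice spheres at 1.4/1.6/1.8/2.0 × Bondi radii,
  1.0 point/Å², points inside another atom's same-scale shell removed.
  Deterministic by construction.
* SVD pseudo-inverse with relative cutoff 1e-6 on singular values; the
  discarded count is recorded on the grid object.  The fit is the plain
  minimum-norm solution; an equality-constrained variant (total charge
  pinned) is available behind a flag.
* SCF: restricted Hartree–Fock, DIIS (subspace 8), convergence 1e-10 in
  energy and 1e-7 on the commutator norm; excitations from CIS.  The
  shipped basis is STO-3G (H, He, C, N, O, F) built from Stewart's
  universal three-Gaussian Slater expansions with the standard molecular
  scale factors.  The engine is closed-shell s/p-only by design; any other
  engine can be swapped in behind the backend contract.
* Degenerate inputs: coincident charge/site pairs raise; empty MM sets give
  zero energies and empty partitions; r_off = 0 sends every charge to the
  long-range side.

## Desk-scale benchmark configuration

The headline runs use a formate anion solute (planar, pi-conjugated,
non-degenerate lowest excitation — the appropriate small analogue of a
solvated chromophore anion; a degenerate lowest pair, as in hydroxide,
would let the "lowest root" deviation measure degeneracy splitting rather
than embedding quality), 10 re-seeded boxes of 200 waters in a 30 Å cube
with the anion bias, ESPCD+LREC at atom-based cutoffs of 5/10/15 Å.
These sizes keep a full benchmark under a couple of minutes on one core
while leaving every claimed tolerance a wide margin.  Built-in solutes
(hydroxide, water, formate) carry package-default force-field reference
charges in the TIP3P/CGenFF spirit; arbitrary solutes arrive as xyzq
files.  No protein-environment fixture ships: enzyme-scale systems are
outside desk scale, and the machinery is environment-agnostic (PDB +
charge-table input is supported).

## Known limitations

* Energies only; no analytic nuclear gradients.
* Multipole expansion stops at dipoles (no quadrupoles), matching the
  models benchmarked.
* No charge-penetration correction: very close unscaled MM charges can
  over-polarize the density, as in any point-charge embedding.
* The RHF/STO-3G engine is a correctness-scale backend, not a production
  level of theory; absolute excitation energies are CIS-quality.
* Non-periodic by design; no Ewald/PME comparison is possible in-package.
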