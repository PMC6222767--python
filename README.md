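# qmmm-embed

Hybrid short/long-range electrostatic embedding for non-periodic QM/MM
calculations, with a benchmark suite that measures how well each embedding
model reproduces an all-charge reference.

## The problem

In electrostatic-embedding QM/MM, every MM point charge enters the QM
one-electron Hamiltonian, and the three-center integrals this requires
scale linearly with the number of charges — expensive for the 10⁴–10⁵
distant charges of a solvated or protein environment, whose collective
effect is nevertheless far too large to drop (tens of kcal/mol around an
anion).  This package implements the hybrid remedy: MM charges within a
cutoff `r_off` of the QM region interact with the explicit electron
density,

    E_short = Σ_A Z_A φ(r_A) − ∫ ρ(r) φ(r) dr,

while charges beyond the cutoff see a compact multipolar representation of
the QM subsystem,

    E_long = Σ_A Σ_m M_A^m F_A^m,

where `M_A^m` are per-atom charges (m = 0) and Cartesian dipoles
(m = 1..3) — from Mulliken population analysis (**MulC/MulCD**) or from an
SVD fit to the molecular electrostatic potential on layered vdW surface
grids (**ESPC/ESPCD**) — and `F_A^m` is the potential/field of the far
charges at the site.  A switching function S(r) (Step, Shift, Switch or
LREC) splits each near-field charge as `q = S q + (1−S) q` between the two
regimes so the energy stays continuous as charges cross the cutoff.
**Truncation**/**Truncation+MMLC** (drop the far field / restore it with
fixed force-field charges) and **mechanical** embedding are included for
comparison.

For the ESP models the far field enters the SCF *exactly* as fixed charges
projected onto the fit grid (`q_s = Σ_Am F_Am (K⁻¹)_Am,s`, with
`Σ_s q_s φ_s ≡ Σ_Am M_A^m F_A^m` as an algebraic identity), so
self-consistency costs nothing; the Mulliken far field contributes a
constant one-electron matrix because its energy is linear in the density
matrix.

The package is aimed at method developers who want a small, fully tested
laboratory for cutoff/switching/multipole choices: it ships a
self-contained restricted Hartree–Fock + CIS engine (McMurchie–Davidson
integrals, STO-3G for H/He/C/N/O/F), a classical *surrogate* backend that
makes every embedding test exact and quantum-chemistry-free, and a seeded
synthetic water-box generator standing in for MD snapshots.

## Worked example

Generate a solvated-hydroxide configuration (150 rigid TIP3P-geometry
waters in a 26 Å box) and evaluate the ESPCD model with LREC switching at
a 10 Å atom-based cutoff:

```bash
qmmm-embed genbox --seed 7 --waters 150 --box 26 --solute hydroxide --out oh_box.xyzq
qmmm-embed energy --model espcd --switch lrec --roff 10 oh_box.xyzq
```

```json
{
  "model": "espcd",
  "switching": "lrec",
  "r_off": 10.0,
  "short_range": -90.64992754424185,
  "long_range": 29.706805036796926,
  "mmlc": 0.0,
  "total": -60.943122507444926,
  "reference_total": -60.93952225150361,
  "deviation": -0.003600255941314856
}
```

All energies are kcal/mol.  `short_range` is the LREC-scaled near field
interacting with the converged electron density, `long_range` the
remaining charges interacting with the ESP-fitted charges+dipoles, and
`total` their sum.  `reference_total` embeds **all** 450 charges in the
density: the hybrid treatment reproduces it to 0.0036 kcal/mol while only
~40% of the charges touched the expensive short-range machinery.

The same machinery is scriptable — `convergence_scan` runs a
model × switching × cutoff grid over many seeded configurations and
reports RMSDs of the electrostatic energy, polarization energy
(first-minus-last SCF cycle), Mulliken/ESP atomic charges, and the lowest
vertical excitation energy against the all-charge reference; see
`qmmm-embed scan --config scan.yaml` and `docs/methods.md`.

ESPCD with a smooth switching function is the recommended combination: at
a 10 Å cutoff it
reproduces reference electrostatic energies to ≲0.01 kcal/mol,
polarization energies to ~10⁻⁶ kcal/mol, atomic charges to ~10⁻⁵ e and
excitation energies to ~10⁻⁴ eV on the synthetic benchmark.

## xyzq format

```
<n_qm> <n_mm> [charge=<int>] [mult=<int>]
element  x  y  z  q  group     # QM block first, group = -1
element  x  y  z  q  group     # MM charges, group >= 0 (one per molecule)
```

Coordinates in Å, charges in e; the QM charge column holds fixed
force-field reference charges (used by the mechanical/MMLC models).
Frames may be concatenated.  PDB input with a companion `serial charge`
table is also supported (one residue = one charge group).

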