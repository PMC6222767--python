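"""Multipolar representations of the QM subsystem.

The long-range side of the hybrid embedding replaces the explicit electron
density by per-atom generalized moments M_A^m — a charge (m = 0) and the
three Cartesian dipole components (m = 1..3) — interacting with the MM
environment through the charge/dipole interaction tensor

    T_A0,B = 1 / |r_A - r_B|
    T_Am,B = (r_A - r_B)_m / |r_A - r_B|^3 ,  m = x, y, z

so that E_long = sum_Am M_A^m F_A^m with F_A^m = sum_B q_B T_Am,B (the local
Taylor expansion of the MM potential: F^0 is the potential, F^{1..3} the
electric-field components at the site).

Sign convention for site dipoles: the stored dipole is the *electron-density*
moment  mu_A = + int (r - r_A) rho_A(r) dr  (rho_A positive).  This is the
negative of the physical charge-distribution dipole of the atomic fragment;
with the tensor above it makes E_long converge to the exact density–charge
Coulomb energy in the far-field limit, which is verified by the
convergence-order property tests.

Two routes produce the moments:

* Mulliken partitioning of the one-particle density matrix (gross
  populations: diagonal block plus all cross terms owned by the atom's basis
  functions, evaluated with the symmetrized density matrix).
* A least-squares fit (via SVD pseudo-inverse) to the molecular
  electrostatic potential sampled on layered van der Waals surface grids
  (ESP charges / charges+dipoles).

The ESP route admits an exact reformulation: projecting the far-field MM
charges onto the fit grid, q_s = sum_Am F_Am (K^-1)_Am,s, reproduces the
multipolar energy identically as sum_s q_s phi_s, which turns the long-range
term into plain external point charges on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .system_io import ANGSTROM_TO_BOHR, MMCharges, QMRegion

#: Bondi van der Waals radii (Angstrom), used for ESP grid shells.
VDW_RADII = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "K": 2.75, "Br": 1.85, "I": 1.98,
}

#: Merz–Kollman-style shell scale factors ("four layers of vdW surfaces").
DEFAULT_SHELLS = (1.4, 1.6, 1.8, 2.0)
DEFAULT_GRID_DENSITY = 1.0  # points per Angstrom^2
SVD_RCOND = 1e-6


def n_components(order: int) -> int:
    if order not in (0, 1):
        raise ValueError("multipole order must be 0 (charges) or 1 (charges+dipoles)")
    return 1 if order == 0 else 4


@dataclass
class MultipoleSet:
    """Per-site generalized moments: charge (e) and optional dipole (e*bohr)."""

    sites: np.ndarray          # Angstrom, one row per QM atom
    M: np.ndarray              # (n_sites, 1) or (n_sites, 4): [q, mux, muy, muz]
    order: int
    method: str                # mulliken | esp | reference_ff | surrogate

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 3)
        self.M = np.asarray(self.M, dtype=float).reshape(len(self.sites), -1)
        if self.M.shape[1] != n_components(self.order):
            raise ValueError(
                f"moment array has {self.M.shape[1]} components per site, "
                f"expected {n_components(self.order)} for order {self.order}"
            )

    @property
    def charges(self) -> np.ndarray:
        return self.M[:, 0]

    @property
    def dipoles(self) -> np.ndarray:
        if self.order == 0:
            raise ValueError("order-0 multipole set stores no dipoles")
        return self.M[:, 1:4]

    def flat(self) -> np.ndarray:
        """Site-major moment vector [q_0, mux_0, ..., q_1, ...]."""
        return self.M.ravel()


@dataclass
class LocalField:
    """Potential and field of the MM environment at the QM sites (a.u.)."""

    phi: np.ndarray            # (n_sites,)
    field: np.ndarray          # (n_sites, 3), components F^{1..3} = E_x, E_y, E_z

    def flat(self, order: int) -> np.ndarray:
        if order == 0:
            return self.phi.copy()
        return np.hstack([self.phi[:, None], self.field]).ravel()

    def __add__(self, other: "LocalField") -> "LocalField":
        return LocalField(self.phi + other.phi, self.field + other.field)


@dataclass
class GridChargeSet:
    """MM charges projected onto the ESP grid (e per grid point)."""

    q_s: np.ndarray


# ---------------------------------------------------------------------------
# Interaction tensors and local fields
# ---------------------------------------------------------------------------


def interaction_tensor(site, source, order: int = 1) -> np.ndarray:
    """T_Am,B components for one site/source pair, atomic units in and out."""
    site = np.asarray(site, dtype=float)
    source = np.asarray(source, dtype=float)
    dr = site - source
    r = np.linalg.norm(dr)
    if r < 1e-12:
        raise ValueError("interaction tensor is singular for coincident points")
    if order == 0:
        return np.array([1.0 / r])
    return np.concatenate([[1.0 / r], dr / r**3])


def interaction_tensor_matrix(sites_bohr: np.ndarray, sources_bohr: np.ndarray,
                              order: int = 1) -> np.ndarray:
    """Vectorized tensor, shape (n_sites, n_components, n_sources), a.u."""
    sites_bohr = np.atleast_2d(sites_bohr)
    sources_bohr = np.atleast_2d(sources_bohr)
    dr = sites_bohr[:, None, :] - sources_bohr[None, :, :]   # (nA, nB, 3)
    r = np.linalg.norm(dr, axis=2)
    if r.size and r.min() < 1e-12:
        a, b = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(f"site {a} coincides with source {b}: singular interaction tensor")
    ncomp = n_components(order)
    T = np.empty((len(sites_bohr), ncomp, len(sources_bohr)))
    T[:, 0, :] = 1.0 / r
    if order == 1:
        T[:, 1:4, :] = np.moveaxis(dr / r[:, :, None] ** 3, 2, 1)
    return T


def local_field(charges: MMCharges, sites_angstrom: np.ndarray, order: int = 1) -> LocalField:
    """Potential/field (a.u.) of a set of MM point charges at the QM sites."""
    sites_b = np.atleast_2d(np.asarray(sites_angstrom, dtype=float)) * ANGSTROM_TO_BOHR
    n_sites = len(sites_b)
    if charges.n_charges == 0:
        return LocalField(np.zeros(n_sites), np.zeros((n_sites, 3)))
    T = interaction_tensor_matrix(sites_b, charges.coords_bohr, order=1)
    phi = T[:, 0, :] @ charges.q
    fld = np.einsum("acb,b->ac", T[:, 1:4, :], charges.q)
    return LocalField(phi, fld)


def multipole_potential(M: MultipoleSet, points_angstrom: np.ndarray) -> np.ndarray:
    """Potential (a.u.) generated by a multipole set at given points.

    phi(s) = sum_A [ q_A / r + mu_A . (r_A - r_s) / r^3 ]  with the module's
    dipole sign convention.
    """
    pts_b = np.atleast_2d(np.asarray(points_angstrom, dtype=float)) * ANGSTROM_TO_BOHR
    K = interaction_tensor_matrix(M.sites * ANGSTROM_TO_BOHR, pts_b, order=M.order)
    # phi_s = sum_Am M_Am K_Am,s
    return np.einsum("am,ams->s", M.M, K)


# ---------------------------------------------------------------------------
# Mulliken charges and dipoles
# ---------------------------------------------------------------------------


def mulliken_multipoles(density, qm: QMRegion, order: int = 1) -> MultipoleSet:
    """Mulliken charges (and atomic dipoles) from a converged density.

    The density handle must expose ``density_matrix`` (with Tr(DS) equal to
    the electron count), ``overlap``, ``moment_integrals`` (<mu|r|nu> in
    bohr, shape (3, n, n)) and ``basis_atom_indices``.  Surrogate densities
    that carry intrinsic site moments are passed through unchanged.
    """
    n_components(order)  # validate
    if hasattr(density, "intrinsic_multipoles"):
        return density.intrinsic_multipoles(order)
    try:
        D = np.asarray(density.density_matrix)
        S = np.asarray(density.overlap)
        R = np.asarray(density.moment_integrals)     # (3, n, n), bohr
        atom_of = np.asarray(density.basis_atom_indices)
    except AttributeError as exc:
        raise TypeError(
            "density handle does not satisfy the Mulliken contract "
            f"(missing {exc})"
        ) from exc

    Dsym = 0.5 * (D + D.T)
    sites_b = qm.coords_bohr
    n_atoms = qm.n_atoms
    M = np.zeros((n_atoms, n_components(order)))
    DS = Dsym * S                     # elementwise: contributions P_mn S_mn
    DR = np.array([Dsym * R[k] for k in range(3)])
    for A in range(n_atoms):
        mask = atom_of == A
        n_elec_A = DS[mask, :].sum()
        M[A, 0] = qm.Z[A] - n_elec_A
        if order == 1:
            # + int (r - r_A) rho_A : electron-density moment (see module doc)
            for k in range(3):
                M[A, 1 + k] = DR[k][mask, :].sum() - sites_b[A, k] * n_elec_A
    return MultipoleSet(sites=qm.coords, M=M, order=order, method="mulliken")


# ---------------------------------------------------------------------------
# ESP grids, fits and grid projection
# ---------------------------------------------------------------------------


@dataclass
class ESPGrid:
    """Fit grid on layered vdW surfaces, with lazily built coupling tensor."""

    points: np.ndarray                     # (n_s, 3) Angstrom
    phi_s: np.ndarray | None = None        # target potentials (a.u.)
    order: int | None = None
    K: np.ndarray | None = None            # (n_moments, n_s)
    pinv_K: np.ndarray | None = None       # (n_moments, n_s): (K^-1)_Am,s
    n_discarded_singular: int = 0
    svd_rcond: float = SVD_RCOND

    @property
    def n_points(self) -> int:
        return len(self.points)

    def build_coupling(self, qm: QMRegion, order: int) -> None:
        """Assemble K_Am,s and its SVD pseudo-inverse for the given order."""
        ncomp = n_components(order)
        n_unknowns = qm.n_atoms * ncomp
        if self.n_points < n_unknowns:
            raise ValueError(
                f"underdetermined ESP fit: {self.n_points} grid points for "
                f"{n_unknowns} unknown moments"
            )
        T = interaction_tensor_matrix(qm.coords_bohr, self.points * ANGSTROM_TO_BOHR, order)
        K = T.reshape(n_unknowns, self.n_points)
        U, s, Vt = np.linalg.svd(K.T, full_matrices=False)
        keep = s > self.svd_rcond * s[0]
        self.n_discarded_singular = int(np.sum(~keep))
        inv_s = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
        # minimum-norm pseudo-inverse of K^T, laid out as (K^-1)_Am,s
        self.pinv_K = (Vt.T * inv_s) @ U.T
        self.K = K
        self.order = order

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        if self.phi_s is not None:
            df["phi"] = self.phi_s
        return df


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def build_esp_grid(qm: QMRegion, shells=DEFAULT_SHELLS,
                   density_per_area: float = DEFAULT_GRID_DENSITY,
                   radii: dict | None = None) -> ESPGrid:
    """Layered vdW-surface grid: per-atom Fibonacci spheres at scaled Bondi
    radii, with points falling inside any other atom's same-scale shell
    removed."""
    radii = radii or VDW_RADII
    try:
        R = np.array([radii[e] for e in qm.elements])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}")

    chunks = []
    for scale in shells:
        shell_R = scale * R
        for a in range(qm.n_atoms):
            r_a = shell_R[a]
            n_pts = max(1, int(round(density_per_area * 4.0 * np.pi * r_a**2)))
            pts = qm.coords[a] + r_a * _fibonacci_sphere(n_pts)
            if qm.n_atoms > 1:
                others = np.arange(qm.n_atoms) != a
                d = cdist(pts, qm.coords[others])
                keep = np.all(d >= shell_R[others][None, :] - 1e-9, axis=1)
                pts = pts[keep]
            chunks.append(pts)
    points = np.vstack(chunks) if chunks else np.zeros((0, 3))
    return ESPGrid(points=points)


def fit_esp_multipoles(grid: ESPGrid, qm: QMRegion, order: int = 1,
                       total_charge: float | None = None) -> MultipoleSet:
    """Least-squares moments reproducing grid.phi_s.

    Default: the minimum-norm solution M = pinv(K^T) phi (plain SVD
    pseudo-inverse).  With *total_charge* given, the fit is instead solved
    under the equality constraint sum_A q_A = total_charge (Lagrange
    multiplier on the KKT system) — an experimentation flag; the plain
    pseudo-inverse is the route used by the hybrid energy models and by the
    grid-projection identity.
    """
    if grid.phi_s is None:
        raise ValueError("grid carries no target potentials phi_s")
    if grid.K is None or grid.order != order:
        grid.build_coupling(qm, order)
    ncomp = n_components(order)
    if total_charge is None:
        M_flat = grid.pinv_K @ grid.phi_s
    else:
        A = grid.K.T                                  # (n_s, n_m)
        C = np.zeros((1, A.shape[1]))
        C[0, ::ncomp] = 1.0                           # picks out the site charges
        kkt = np.block([[A.T @ A, C.T], [C, np.zeros((1, 1))]])
        rhs = np.concatenate([A.T @ grid.phi_s, [total_charge]])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        M_flat = sol[: A.shape[1]]
    M = M_flat.reshape(qm.n_atoms, ncomp)
    return MultipoleSet(sites=qm.coords, M=M, order=order, method="esp")


def project_mm_to_grid(mm_far: MMCharges, grid: ESPGrid, qm: QMRegion,
                       order: int = 1) -> GridChargeSet:
    """Project far-field MM charges onto the ESP grid:
    q_s = sum_Am F_Am (K^-1)_Am,s  with F the far-field local Taylor
    expansion at the QM sites.  By construction sum_s q_s phi_s equals the
    multipolar energy sum_Am M_Am F_Am for any phi_s and its fitted moments.
    """
    if grid.pinv_K is None or grid.order != order:
        grid.build_coupling(qm, order)
    if mm_far.n_charges == 0:
        return GridChargeSet(np.zeros(grid.n_points))
    F = local_field(mm_far, qm.coords, order=1).flat(order)
    return GridChargeSet(F @ grid.pinv_K)


def esp_multipoles_from_density(density, qm: QMRegion, order: int = 1,
                                grid: ESPGrid | None = None,
                                shells=DEFAULT_SHELLS,
                                density_per_area: float = DEFAULT_GRID_DENSITY,
                                ) -> tuple[MultipoleSet, ESPGrid]:
    """Convenience: build (or reuse) a grid, evaluate the density's ESP on
    it through the owning backend, and fit moments."""
    if grid is None:
        grid = build_esp_grid(qm, shells=shells, density_per_area=density_per_area)
    if grid.phi_s is None:
        grid.phi_s = density.backend.esp_on_points(density, qm, grid.points)
    return fit_esp_multipoles(grid, qm, order), grid
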