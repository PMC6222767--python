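"""Backend contract for SCF/excited-state engines, plus a classical surrogate.

Every embedding model needs four capabilities from a quantum-chemistry
backend: converging an SCF in the presence of an embedding operator,
evaluating the molecular electrostatic potential on points, contracting the
density with external point charges, and (optionally) vertical excitation
energies.  The :class:`BackendContract` base class fixes those signatures.

The :class:`SurrogateBackend` implements the same contract with a *classical*
stand-in density — either an analytic multipole set or a rigid cloud of
point charges assigned to the QM sites.  Its "SCF" is a no-op (the density
never polarizes), which makes every embedding-model test exact and
quantum-chemistry-free: potentials, fields and energies reduce to closed-form
Coulomb arithmetic that mirrors the multipole module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .multipole_rep import MultipoleSet, interaction_tensor_matrix, multipole_potential
from .system_io import ANGSTROM_TO_BOHR, MMCharges, QMRegion


class CapabilityError(RuntimeError):
    """The backend does not advertise the requested capability."""


class SCFConvergenceError(RuntimeError):
    def __init__(self, message: str, n_cycles: int | None = None):
        super().__init__(message)
        self.n_cycles = n_cycles


@dataclass
class EmbeddingOperatorSpec:
    """External electrostatic operator entering the one-electron Hamiltonian.

    ``charge_coords``/``charge_values`` are plain external point charges
    (Angstrom / e).  ``one_electron_matrix`` is an optional explicit matrix
    contribution in a.u. (used by the Mulliken long-range models, whose
    energy is linear in the density matrix); ``nuclear_energy_shift`` (a.u.)
    collects density-independent terms that belong to the same operator.
    """

    charge_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    charge_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    one_electron_matrix: np.ndarray | None = None
    nuclear_energy_shift: float = 0.0

    def __post_init__(self):
        self.charge_coords = np.asarray(self.charge_coords, dtype=float).reshape(-1, 3)
        self.charge_values = np.asarray(self.charge_values, dtype=float).reshape(-1)
        if len(self.charge_coords) != len(self.charge_values):
            raise ValueError("operator charge coords/values length mismatch")

    @property
    def n_charges(self) -> int:
        return len(self.charge_values)

    def as_mm_charges(self) -> MMCharges:
        return MMCharges(self.charge_coords, self.charge_values,
                         np.zeros(self.n_charges, dtype=int))

    @staticmethod
    def vacuum() -> "EmbeddingOperatorSpec":
        return EmbeddingOperatorSpec()


class BackendContract:
    """Abstract backend: advertised capabilities must be callable."""

    capabilities: dict = {
        "scf": False, "esp_on_points": False,
        "density_charge_interaction": False, "tddft": False,
    }

    def require(self, cap: str) -> None:
        if not self.capabilities.get(cap, False):
            raise CapabilityError(f"backend {type(self).__name__} lacks capability {cap!r}")

    def converged_scf(self, qm: QMRegion, operator: EmbeddingOperatorSpec,
                      initial=None):
        raise NotImplementedError

    def esp_on_points(self, density, qm: QMRegion, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def density_charge_interaction(self, density, qm: QMRegion,
                                   charges: MMCharges) -> float:
        raise NotImplementedError

    def excitation_energies(self, density, qm: QMRegion,
                            operator: EmbeddingOperatorSpec, n_states: int = 1):
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Surrogate backend
# ---------------------------------------------------------------------------


@dataclass
class SurrogateDensity:
    """A frozen classical density: either a multipole set or a charge cloud."""

    backend: "SurrogateBackend"
    tag: str = "surrogate"

    def intrinsic_multipoles(self, order: int = 1) -> MultipoleSet:
        """Exact site moments of the source (plays the role of a Mulliken
        analysis for surrogate densities)."""
        return self.backend.site_multipoles(order)


class SurrogateBackend(BackendContract):
    """Classical stand-in engine whose density never responds.

    Construct from either a :class:`MultipoleSet` (analytic charge+dipole
    field at the QM sites) or a rigid cloud of point charges
    (``cloud_coords`` in Angstrom, ``cloud_charges`` in e).  The cloud mode
    represents an exact charge distribution — including moments beyond
    dipole — so it serves as the reference for far-field convergence-order
    checks; its per-site moments are the exact multipole expansion of the
    cloud about the nearest QM site.
    """

    capabilities = {
        "scf": True, "esp_on_points": True,
        "density_charge_interaction": True, "tddft": False,
    }

    def __init__(self, qm: QMRegion, multipoles: MultipoleSet | None = None,
                 cloud_coords: np.ndarray | None = None,
                 cloud_charges: np.ndarray | None = None):
        if (multipoles is None) == (cloud_coords is None):
            raise ValueError("provide exactly one of multipoles or cloud_coords/cloud_charges")
        self.qm = qm
        self.multipoles = multipoles
        if cloud_coords is not None:
            self.cloud_coords = np.asarray(cloud_coords, dtype=float).reshape(-1, 3)
            self.cloud_charges = np.asarray(cloud_charges, dtype=float).reshape(-1)
        else:
            self.cloud_coords = None
            self.cloud_charges = None

    # -- density construction ------------------------------------------------

    def density(self) -> SurrogateDensity:
        return SurrogateDensity(backend=self)

    def site_multipoles(self, order: int = 1) -> MultipoleSet:
        """Exact per-site moments of the surrogate source."""
        if self.multipoles is not None:
            if order == self.multipoles.order:
                return self.multipoles
            if order == 0:
                return MultipoleSet(self.multipoles.sites, self.multipoles.M[:, :1],
                                    order=0, method=self.multipoles.method)
            M = np.zeros((len(self.multipoles.sites), 4))
            M[:, 0] = self.multipoles.charges
            return MultipoleSet(self.multipoles.sites, M, order=1,
                                method=self.multipoles.method)
        sites = self.qm.coords
        owner = np.argmin(cdist(self.cloud_coords, sites), axis=1)
        ncomp = 1 if order == 0 else 4
        M = np.zeros((len(sites), ncomp))
        for A in range(len(sites)):
            mask = owner == A
            q = self.cloud_charges[mask]
            M[A, 0] = q.sum()
            if order == 1:
                # stored dipole = -(physical fragment dipole); see multipole_rep
                dr = (self.cloud_coords[mask] - sites[A]) * ANGSTROM_TO_BOHR
                M[A, 1:4] = -(q[:, None] * dr).sum(axis=0)
        return MultipoleSet(sites=sites, M=M, order=order, method="surrogate")

    # -- potentials ----------------------------------------------------------

    def potential_at(self, points_angstrom: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_angstrom, dtype=float))
        if self.multipoles is not None:
            return multipole_potential(self.multipoles, pts)
        T = interaction_tensor_matrix(self.cloud_coords * ANGSTROM_TO_BOHR,
                                      pts * ANGSTROM_TO_BOHR, order=0)
        return np.einsum("b,bs->s", self.cloud_charges, T[:, 0, :])

    # -- contract implementation ----------------------------------------------

    def converged_scf(self, qm: QMRegion, operator: EmbeddingOperatorSpec,
                      initial=None):
        """No-op 'SCF': the frozen source cannot polarize, so the first-cycle
        and converged energies coincide (interaction with the operator)."""
        if operator.one_electron_matrix is not None:
            raise CapabilityError("surrogate backend has no basis to apply a matrix operator")
        density = initial if initial is not None else self.density()
        e = self.density_charge_interaction(density, qm, operator.as_mm_charges())
        e += operator.nuclear_energy_shift
        return density, e, e

    def esp_on_points(self, density, qm: QMRegion, points: np.ndarray) -> np.ndarray:
        return self.potential_at(points)

    def density_charge_interaction(self, density, qm: QMRegion,
                                   charges: MMCharges) -> float:
        if charges.n_charges == 0:
            return 0.0
        return float(charges.q @ self.potential_at(charges.coords))

    def excitation_energies(self, density, qm, operator, n_states: int = 1):
        self.require("tddft")
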