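"""QM/MM electrostatic energy models and the hybrid embedding scheme.

Model taxonomy (long-range treatment of far-field MM charges):

===============  ===========================================================
``reference``    all MM charges interact with the explicit QM density
``truncation``   far-field charges dropped entirely
``truncation_mmlc``  far field treated classically with fixed force-field
                 charges on QM atoms (MM-level long-range correction)
``mulc``/``mulcd``   Mulliken charges / charges+dipoles of the QM density
``espc``/``espcd``   ESP-fitted charges / charges+dipoles of the QM density
``mechanical``   the whole QM/MM electrostatics at the MM level
===============  ===========================================================

The hybrid energy splits the environment at a cutoff r_off (distance of
each MM charge to its closest QM atom): near-field charges, scaled by a
switching function, interact with the explicit density (short range); their
switching complement and all far-field charges are handed to the model's
long-range representation.  Charge splitting conserves every MM charge
exactly, so the total electrostatic energy varies continuously as charges
cross the cutoff whenever the switching function is continuous.

For the ESP models the long-range term can be recast exactly as fixed
point charges projected onto the fit grid; those enter the one-electron
Hamiltonian like ordinary external charges, which keeps the SCF variational
with no response terms.  The Mulliken long-range energy is linear in the
density matrix, so it contributes a constant one-electron matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cutoff_switching import (CutoffPartition, SplitCharges, SwitchingSpec,
                               partition_charges, split_charges)
from .multipole_rep import (ESPGrid, MultipoleSet, LocalField, build_esp_grid,
                            esp_multipoles_from_density, local_field,
                            mulliken_multipoles, project_mm_to_grid)
from .qm_adapter import EmbeddingOperatorSpec
from .system_io import (HARTREE_TO_KCALMOL, EnergyReport, MMCharges, QMRegion)

MODEL_NAMES = ("reference", "truncation", "truncation_mmlc",
               "mulc", "mulcd", "espc", "espcd", "mechanical")


@dataclass(frozen=True)
class EmbeddingModel:
    name: str

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.lower())
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown embedding model {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def order(self) -> int | None:
        """Multipole truncation order of the long-range representation."""
        return {"mulc": 0, "espc": 0, "mulcd": 1, "espcd": 1}.get(self.name)

    @property
    def long_range(self) -> str:
        if self.name in ("mulc", "mulcd"):
            return "mulliken"
        if self.name in ("espc", "espcd"):
            return "esp"
        if self.name == "truncation_mmlc":
            return "mm"
        return "none"


def _as_model(model) -> EmbeddingModel:
    return model if isinstance(model, EmbeddingModel) else EmbeddingModel(str(model))


# ---------------------------------------------------------------------------
# Elementary energy expressions
# ---------------------------------------------------------------------------


def mechanical_energy(qm: QMRegion, mm: MMCharges) -> float:
    """Coulomb energy (kcal/mol) between fixed reference charges on the QM
    atoms and the MM point charges."""
    if qm.ff_charges is None:
        raise ValueError("mechanical embedding requires ff_charges on the QM region")
    if mm.n_charges == 0:
        return 0.0
    d = cdist(qm.coords_bohr, mm.coords_bohr)
    if d.min() < 1e-10:
        raise ValueError("QM and MM sites coincide in mechanical energy")
    e_au = float(qm.ff_charges @ (1.0 / d) @ mm.q)
    return e_au * HARTREE_TO_KCALMOL


def density_embedding_energy(density, qm: QMRegion, mm: MMCharges) -> float:
    """Explicit density–point-charge Coulomb energy (kcal/mol): nuclei plus
    electron density of the QM region against the given MM charges."""
    if mm.n_charges == 0:
        return 0.0
    e_au = density.backend.density_charge_interaction(density, qm, mm)
    return e_au * HARTREE_TO_KCALMOL


def multipolar_energy(M: MultipoleSet, F: LocalField) -> float:
    """E = sum_A sum_m M_A^m F_A^m in kcal/mol (bilinear in moments/field)."""
    if len(M.sites) != len(F.phi):
        raise ValueError("multipole set and local field have different site counts")
    e_au = float(M.charges @ F.phi)
    if M.order == 1:
        e_au += float(np.sum(M.dipoles * F.field))
    return e_au * HARTREE_TO_KCALMOL


def mmlc_correction(qm: QMRegion, mm_far: MMCharges) -> float:
    """MM-level long-range correction: mechanical energy restricted to the
    far field (kcal/mol)."""
    return mechanical_energy(qm, mm_far)


# ---------------------------------------------------------------------------
# Hybrid scheme
# ---------------------------------------------------------------------------


def _split_sets(mm: MMCharges, part: CutoffPartition, split: SplitCharges,
                tol: float = 0.0):
    """(near-scaled charges q_I, long-range charges q_II ∪ q_far)."""
    near_coords = mm.coords[part.near_idx]
    near_groups = mm.group_id[part.near_idx]
    keep_I = np.abs(split.q_I) > tol
    near_scaled = MMCharges(near_coords[keep_I], split.q_I[keep_I], near_groups[keep_I])
    lr_coords = np.vstack([near_coords, mm.coords[part.far_idx]])
    lr_q = np.concatenate([split.q_II, mm.q[part.far_idx]])
    lr_groups = np.concatenate([near_groups, mm.group_id[part.far_idx]])
    keep_II = np.abs(lr_q) > tol
    long_range = MMCharges(lr_coords[keep_II], lr_q[keep_II], lr_groups[keep_II])
    return near_scaled, long_range


def long_range_multipoles(density, qm: QMRegion, model: EmbeddingModel,
                          grid: ESPGrid | None = None) -> tuple[MultipoleSet, ESPGrid | None]:
    """The multipole set a given model uses for its long-range term."""
    model = _as_model(model)
    if model.long_range == "mulliken":
        return mulliken_multipoles(density, qm, model.order), None
    if model.long_range == "esp":
        M, grid = esp_multipoles_from_density(density, qm, model.order, grid=grid)
        return M, grid
    raise ValueError(f"model {model.name} has no multipolar long-range term")


def hybrid_energy(density, qm: QMRegion, mm: MMCharges, model,
                  spec: SwitchingSpec, mode: str = "atom",
                  grid: ESPGrid | None = None) -> EnergyReport:
    """Hybrid QM/MM electrostatic energy for one model/switching/cutoff.

    Short range: explicit density embedding of the scaled near-field charges.
    Long range: the model's representation applied to the switching
    complement plus the far field.  Components are reported separately in
    kcal/mol and sum to the total.
    """
    model = _as_model(model)
    if model.name == "mechanical":
        raise ValueError("use mechanical_energy for the mechanical model")

    if model.name == "reference":
        short = density_embedding_energy(density, qm, mm)
        components = {"short_range": short, "long_range": 0.0, "mmlc": 0.0,
                      "total": short}
        rep = EnergyReport(model.name, spec.scheme, spec.r_off, components)
        rep.validate()
        return rep

    part = partition_charges(mm, qm, spec, mode=mode)
    split = split_charges(part, mm, spec)
    near_scaled, long_range = _split_sets(mm, part, split)

    short = density_embedding_energy(density, qm, near_scaled)
    long_e = 0.0
    mmlc = 0.0
    if model.long_range == "mm":
        mmlc = mmlc_correction(qm, long_range)
    elif model.long_range in ("mulliken", "esp") and long_range.n_charges:
        if model.long_range == "esp":
            M, grid = esp_multipoles_from_density(density, qm, model.order, grid=grid)
        else:
            M = mulliken_multipoles(density, qm, model.order)
        F = local_field(long_range, qm.coords, order=1)
        long_e = multipolar_energy(M, F)

    components = {"short_range": short, "long_range": long_e, "mmlc": mmlc,
                  "total": short + long_e + mmlc}
    rep = EnergyReport(model.name, spec.scheme, spec.r_off, components)
    rep.validate()
    return rep


# ---------------------------------------------------------------------------
# Embedding operator and polarization
# ---------------------------------------------------------------------------


def _mulliken_long_range_matrix(density, qm: QMRegion, F: LocalField, order: int):
    """Constant one-electron matrix whose trace with D gives the electronic
    part of the Mulliken long-range energy, plus the nuclear shift."""
    S = np.asarray(density.overlap)
    R = np.asarray(density.moment_integrals)
    atom_of = np.asarray(density.basis_atom_indices)
    sites_b = qm.coords_bohr
    h = np.zeros_like(S)
    for A in range(qm.n_atoms):
        rows = atom_of == A
        h[rows, :] += -F.phi[A] * S[rows, :]
        if order == 1:
            for k in range(3):
                h[rows, :] += F.field[A, k] * (R[k][rows, :] - sites_b[A, k] * S[rows, :])
    h = 0.5 * (h + h.T)
    shift = float(qm.Z @ F.phi)
    return h, shift


def build_embedding_operator(model, qm: QMRegion, mm: MMCharges,
                             spec: SwitchingSpec, mode: str = "atom",
                             grid: ESPGrid | None = None,
                             density=None) -> EmbeddingOperatorSpec:
    """Assemble the operator entering the one-electron Hamiltonian.

    Scaled near-field charges always enter as external point charges.  The
    long-range term enters as projected grid charges (ESP models; exact by
    the grid-projection identity and density-independent), as a constant
    one-electron matrix plus nuclear shift (Mulliken models; the energy is
    linear in the density matrix so no response term arises), or not at all
    (truncation / MMLC, whose long-range piece is a constant).  The
    ``reference`` model embeds every MM charge unscaled.
    """
    model = _as_model(model)
    if model.name == "mechanical":
        raise ValueError("mechanical embedding defines no QM operator")
    if model.name == "reference":
        return EmbeddingOperatorSpec(mm.coords.copy(), mm.q.copy())

    part = partition_charges(mm, qm, spec, mode=mode)
    split = split_charges(part, mm, spec)
    near_scaled, long_range = _split_sets(mm, part, split)

    coords = [near_scaled.coords]
    values = [near_scaled.q]
    one_e = None
    shift = 0.0

    if model.long_range == "esp" and long_range.n_charges:
        if grid is None:
            grid = build_esp_grid(qm)
        if grid.pinv_K is None or grid.order != model.order:
            grid.build_coupling(qm, model.order)
        q_s = project_mm_to_grid(long_range, grid, qm, model.order).q_s
        coords.append(grid.points)
        values.append(q_s)
    elif model.long_range == "mulliken" and long_range.n_charges:
        if density is None:
            raise ValueError("Mulliken long-range operator needs a density handle "
                             "to supply overlap/moment integrals")
        F = local_field(long_range, qm.coords, order=1)
        one_e, shift = _mulliken_long_range_matrix(density, qm, F, model.order)

    return EmbeddingOperatorSpec(
        charge_coords=np.vstack(coords) if coords else np.zeros((0, 3)),
        charge_values=np.concatenate(values) if values else np.zeros(0),
        one_electron_matrix=one_e,
        nuclear_energy_shift=shift,
    )


def polarization_energy(backend, qm: QMRegion, operator: EmbeddingOperatorSpec,
                        start_density) -> float:
    """Orbital-relaxation energy (kcal/mol) under the given operator,
    measured as converged minus first-cycle SCF energy starting from
    *start_density* (the reference-scheme converged density).  Non-positive
    by the variational principle; its magnitude quantifies how far the
    operator distorts the wavefunction away from the starting one."""
    _, e_first, e_conv = backend.converged_scf(qm, operator, initial=start_density)
    return (e_conv - e_first) * HARTREE_TO_KCALMOL
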