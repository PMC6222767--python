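"""Synthetic solvated systems and model/switching/cutoff convergence scans.

The benchmark protocol compares every hybrid embedding model against the
all-charge density-embedding reference on an ensemble of solvated-solute
configurations: per configuration the reference SCF is converged first, the
hybrid electrostatic energy is evaluated with the reference density, the
SCF is re-converged under each model's embedding operator starting from the
reference orbitals (polarization energy = first minus last cycle), and
population / excited-state properties of the relaxed density are compared
with the reference ones.  Root-mean-square deviations over configurations
are reported per (model, switching scheme, cutoff) cell.

Configurations come from a seeded synthetic water-box generator (rigid
3-site waters with the TIP3P geometry and charges, random placement and
orientation, optional hydrogen-toward-solute orientation bias emulating the
solvation shell of an anion) rather than from molecular dynamics; the RMSD
semantics are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cutoff_switching import SwitchingSpec
from .embedding_models import (_as_model, build_embedding_operator,
                               hybrid_energy, polarization_energy)
from .multipole_rep import (LocalField, esp_multipoles_from_density,
                            local_field, mulliken_multipoles)
from .qm_adapter import BackendContract, EmbeddingOperatorSpec
from .system_io import MMCharges, QMRegion

# Rigid 3-site water: TIP3P geometry (r_OH = 0.9572 A, HOH angle 104.52 deg)
# and charges (O -0.834 e, H +0.417 e).
TIP3P_R_OH = 0.9572
TIP3P_ANGLE_DEG = 104.52
TIP3P_Q = np.array([-0.834, 0.417, 0.417])
_MIN_OO = 2.5  # A, water–water overlap floor


def _water_template() -> np.ndarray:
    """O at origin; H–O–H bisector along +x."""
    half = np.deg2rad(TIP3P_ANGLE_DEG) / 2.0
    h1 = TIP3P_R_OH * np.array([np.cos(half), np.sin(half), 0.0])
    h2 = TIP3P_R_OH * np.array([np.cos(half), -np.sin(half), 0.0])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


@dataclass
class BoxSpec:
    """Synthetic solvation box around a solute placed at the origin."""

    box_length: float              # A, cube edge
    n_waters: int
    solute_exclusion_radius: float = 2.6   # A, O-to-solute floor
    orientation_bias: str = "none"         # none | anion
    seed: int = 0

    def __post_init__(self):
        if self.orientation_bias not in ("none", "anion"):
            raise ValueError("orientation_bias must be 'none' or 'anion'")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1.0
    return Q


def _rotation_aligning(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector v_from onto unit vector v_to."""
    c = float(np.dot(v_from, v_to))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        axis = np.array([1.0, 0.0, 0.0])
        if abs(v_from[0]) > 0.9:
            axis = np.array([0.0, 1.0, 0.0])
        axis -= v_from * np.dot(axis, v_from)
        axis /= np.linalg.norm(axis)
        return -np.eye(3) + 2.0 * np.outer(axis, axis)  # 180 deg about axis
    axis = np.cross(v_from, v_to)
    s = np.linalg.norm(axis)
    axis /= s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def generate_water_box(spec: BoxSpec, solute: QMRegion) -> MMCharges:
    """Pack rigid waters (one charge group each) around the solute.

    Oxygen positions are drawn uniformly in the cube centred on the origin,
    rejected when closer than the exclusion radius to any solute atom or
    than the O–O floor to an already placed water.  Orientations are uniform
    random; with the anion bias each water is instead rotated so one O–H
    bond points at the nearest solute atom, with probability
    exp(-(d - r_contact) / 3 A) decaying with the O–solute distance d — a
    cartoon of the hydrogen-toward-anion ordering of a real solvation shell.
    """
    rng = np.random.default_rng(spec.seed)
    template = _water_template()
    half_box = spec.box_length / 2.0
    placed_O: list[np.ndarray] = []
    coords, groups = [], []
    max_attempts = 2000 * max(spec.n_waters, 1)
    attempts = 0
    while len(placed_O) < spec.n_waters:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"failed to pack {spec.n_waters} waters in a {spec.box_length} A box "
                f"after {max_attempts} attempts"
            )
        pos = rng.uniform(-half_box, half_box, size=3)
        d_solute = np.linalg.norm(solute.coords - pos, axis=1)
        if d_solute.min() < spec.solute_exclusion_radius:
            continue
        if placed_O and np.min(np.linalg.norm(np.array(placed_O) - pos, axis=1)) < _MIN_OO:
            continue

        rot = _random_rotation(rng)
        if spec.orientation_bias == "anion":
            d = float(d_solute.min())
            p = np.exp(-max(0.0, d - spec.solute_exclusion_radius) / 3.0)
            if rng.uniform() < p:
                target = solute.coords[np.argmin(d_solute)] - pos
                target /= np.linalg.norm(target)
                oh = rot @ (template[1] / np.linalg.norm(template[1]))
                rot = _rotation_aligning(oh, target) @ rot
        mol = pos + template @ rot.T
        placed_O.append(pos)
        coords.append(mol)
        groups.extend([len(placed_O) - 1] * 3)

    return MMCharges(np.vstack(coords), np.tile(TIP3P_Q, spec.n_waters),
                     np.array(groups, dtype=int))


def rmsd(values, reference) -> float:
    """Root-mean-square deviation between two equal-length sequences."""
    v = np.asarray(values, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if v.shape != r.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {r.shape}")
    if v.size == 0:
        raise ValueError("rmsd of empty sequences")
    return float(np.sqrt(np.mean((v - r) ** 2)))


def cutoff_mode_for(scheme: str) -> str:
    """Atom-based cutoffs with smooth switching, group-based with Step
    (whole charge groups keep the near field from acquiring artificial net
    charges when no scaling smooths the boundary)."""
    return "group" if scheme == "step" else "atom"


# ---------------------------------------------------------------------------
# Per-configuration reference and scheme evaluation
# ---------------------------------------------------------------------------


@dataclass
class _Reference:
    density: object
    e_elec: float                  # kcal/mol, all charges density-embedded
    mulliken_q: np.ndarray
    esp_q: np.ndarray
    excitations: np.ndarray | None


def _reference_quantities(qm: QMRegion, mm: MMCharges, backend: BackendContract,
                          n_states: int) -> _Reference:
    op = EmbeddingOperatorSpec(mm.coords, mm.q)
    density, _, _ = backend.converged_scf(qm, op)
    e_elec = hybrid_energy(density, qm, mm, "reference",
                           SwitchingSpec("step", r_off=0.0)).total
    mul_q = mulliken_multipoles(density, qm, 0).charges
    esp_q = esp_multipoles_from_density(density, qm, 0)[0].charges
    exc = None
    if backend.capabilities.get("tddft") and n_states > 0:
        exc = backend.excitation_energies(density, qm, op, n_states)
    return _Reference(density, e_elec, mul_q, esp_q, exc)


def _scheme_quantities(qm, mm, model, spec, mode, backend, ref: _Reference,
                       n_states: int):
    model = _as_model(model)
    rep = hybrid_energy(ref.density, qm, mm, model, spec, mode=mode)
    out = {"e_elec": rep.total, "polarization": 0.0,
           "mulliken_q": ref.mulliken_q, "esp_q": ref.esp_q,
           "excitations": ref.excitations}
    if not backend.capabilities.get("scf"):
        return out
    op = build_embedding_operator(model, qm, mm, spec, mode=mode,
                                  density=ref.density)
    out["polarization"] = polarization_energy(backend, qm, op, ref.density)
    relaxed, _, _ = backend.converged_scf(qm, op, initial=ref.density)
    if hasattr(relaxed, "density_matrix"):
        out["mulliken_q"] = mulliken_multipoles(relaxed, qm, 0).charges
        out["esp_q"] = esp_multipoles_from_density(relaxed, qm, 0)[0].charges
        if ref.excitations is not None:
            out["excitations"] = backend.excitation_energies(relaxed, qm, op, n_states)
    return out


def convergence_scan(configs, models, switchings, cutoffs,
                     backend: BackendContract, n_states: int = 1,
                     on_error: str = "mark") -> pd.DataFrame:
    """Run the full benchmark grid and report RMSDs over configurations.

    *configs* is a list of (QMRegion, MMCharges).  Returns a DataFrame with
    one row per (model, switching, r_off) holding the RMSD of the hybrid
    electrostatic energy and polarization energy (kcal/mol), Mulliken and
    ESP atomic charges (e, pooled over atoms and configurations) and the
    lowest vertical excitation energies (eV) against the all-charge
    reference.  A backend failure marks the cell and the scan continues.
    """
    if len(configs) < 1:
        raise ValueError("convergence_scan needs at least one configuration")
    refs = [_reference_quantities(qm, mm, backend, n_states) for qm, mm in configs]

    rows = []
    for model in models:
        model = _as_model(model)
        for scheme in switchings:
            mode = cutoff_mode_for(scheme)
            for r_off in cutoffs:
                spec = SwitchingSpec(scheme, r_off=float(r_off))
                cells = []
                failed = False
                for (qm, mm), ref in zip(configs, refs):
                    try:
                        cells.append(_scheme_quantities(qm, mm, model, spec, mode,
                                                        backend, ref, n_states))
                    except Exception:
                        if on_error == "raise":
                            raise
                        failed = True
                        break
                row = {"model": model.name, "switching": scheme, "r_off": float(r_off),
                       "failed": failed}
                if not failed:
                    row["rmsd_energy"] = rmsd([c["e_elec"] for c in cells],
                                              [r.e_elec for r in refs])
                    row["rmsd_polarization"] = rmsd(
                        [c["polarization"] for c in cells], [0.0] * len(cells))
                    row["rmsd_mulliken_q"] = rmsd(
                        np.concatenate([c["mulliken_q"] for c in cells]),
                        np.concatenate([r.mulliken_q for r in refs]))
                    row["rmsd_esp_q"] = rmsd(
                        np.concatenate([c["esp_q"] for c in cells]),
                        np.concatenate([r.esp_q for r in refs]))
                    if refs[0].excitations is not None:
                        row["rmsd_excitation"] = rmsd(
                            np.concatenate([c["excitations"] for c in cells]),
                            np.concatenate([r.excitations for r in refs]))
                rows.append(row)
    return pd.DataFrame(rows)


def site_potential_diagnostics(qm: QMRegion, mm: MMCharges, part, split
                               ) -> tuple[LocalField, LocalField]:
    """Atom-site potentials/fields from the scaled near field vs the full
    environment (both in a.u.), for inspecting how well a truncated,
    switching-scaled near field reproduces the embedding potential."""
    near_coords = mm.coords[part.near_idx]
    near = MMCharges(near_coords, split.q_I, mm.group_id[part.near_idx])
    mask = np.abs(near.q) > 0
    scaled = local_field(near.subset(np.flatnonzero(mask)), qm.coords, 1) \
        if mask.any() else LocalField(np.zeros(qm.n_atoms), np.zeros((qm.n_atoms, 3)))
    full = local_field(mm, qm.coords, 1) if mm.n_charges else \
        LocalField(np.zeros(qm.n_atoms), np.zeros((qm.n_atoms, 3)))
    return scaled, full


# ---------------------------------------------------------------------------
# Built-in desk-scale solutes
# ---------------------------------------------------------------------------


def builtin_solute(name: str) -> QMRegion:
    """Small solutes for desk-scale benchmarks (coordinates in Angstrom).

    ``hydroxide`` is the default benchmark anion; ``water`` a neutral
    counterpart; ``formate`` a slightly larger delocalized anion.
    """
    name = name.lower()
    if name == "hydroxide":
        return QMRegion(elements=["O", "H"], coords=[[0, 0, 0], [0, 0, 0.97]],
                        ff_charges=[-1.32, 0.32], net_charge=-1)
    if name == "water":
        half = np.deg2rad(TIP3P_ANGLE_DEG) / 2.0
        h = TIP3P_R_OH * np.array([np.cos(half), np.sin(half), 0.0])
        h2 = TIP3P_R_OH * np.array([np.cos(half), -np.sin(half), 0.0])
        return QMRegion(elements=["O", "H", "H"],
                        coords=[[0, 0, 0], h.tolist(), h2.tolist()],
                        ff_charges=[-0.834, 0.417, 0.417], net_charge=0)
    if name == "formate":
        # planar HCO2-, idealized geometry
        return QMRegion(
            elements=["C", "O", "O", "H"],
            coords=[[0.0, 0.0, 0.0], [1.13, 0.74, 0.0], [-1.13, 0.74, 0.0],
                    [0.0, -1.11, 0.0]],
            ff_charges=[0.52, -0.76, -0.76, 0.0], net_charge=-1)
    raise ValueError(f"unknown built-in solute {name!r}")
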