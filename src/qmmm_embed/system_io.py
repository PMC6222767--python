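"""System input/output and unit conventions.

This module owns every unit constant used by the package.  Internal
computation throughout the package is carried out in Hartree atomic units;
user-facing coordinates are Angstrom, charges are elementary charges and
energies are kcal/mol.

Two text formats are supported for complete QM/MM systems:

``xyzq``
    A simple self-describing dialect.  The header line carries the QM and MM
    atom counts plus optional ``key=value`` metadata (``charge``, ``mult``)::

        <n_qm> <n_mm> [charge=<int>] [mult=<int>]
        element  x  y  z  q  group      (QM block first, group = -1)
        element  x  y  z  q  group      (MM block, group >= 0)

    Coordinates in Angstrom, charges in e.  For QM atoms the charge column
    holds the fixed force-field reference charge (used by mechanical
    embedding and the MM-level long-range correction); ``group`` is ``-1``
    for QM atoms and a non-negative charge-group label (one water molecule,
    one residue, one ion) for MM atoms.  Multiple frames may be concatenated
    in one file.

``pdb`` + companion charge table
    Standard PDB columns for coordinates; MM charges come from a two-column
    whitespace table (atom serial, charge in e).  One residue maps to one
    charge group.  QM membership is declared by atom serial numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Unit constants (single point of definition for the whole package)
# ---------------------------------------------------------------------------

BOHR_IN_ANGSTROM = 0.529177210903       # 1 bohr in Angstrom (CODATA 2018)
HARTREE_IN_KCALMOL = 627.509474         # 1 hartree in kcal/mol
HARTREE_IN_EV = 27.211386245988         # 1 hartree in eV

ANGSTROM_TO_BOHR = 1.0 / BOHR_IN_ANGSTROM
HARTREE_TO_KCALMOL = HARTREE_IN_KCALMOL

#: symbol -> nuclear charge
ELEMENT_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}

_Z_TO_ELEMENT = {z: s for s, z in ELEMENT_Z.items()}

# Unit tags recognized by to_atomic_units / from_atomic_units: the factor
# converts the tagged unit INTO the corresponding atomic unit.
_TO_AU = {
    "angstrom": ANGSTROM_TO_BOHR,
    "bohr": 1.0,
    "kcal/mol": 1.0 / HARTREE_IN_KCALMOL,
    "hartree": 1.0,
    "ev": 1.0 / HARTREE_IN_EV,
    "e": 1.0,
}


def to_atomic_units(x, unit: str):
    """Convert a length/energy/charge quantity into atomic units.

    ``unit`` names the unit *x* is currently expressed in
    (``angstrom``, ``bohr``, ``kcal/mol``, ``hartree``, ``ev``, ``e``).
    """
    key = unit.lower()
    if key not in _TO_AU:
        raise ValueError(f"unknown unit tag {unit!r}")
    return np.asarray(x, dtype=float) * _TO_AU[key] if np.ndim(x) else float(x) * _TO_AU[key]


def from_atomic_units(x, unit: str):
    """Inverse of :func:`to_atomic_units` (exact to floating rounding)."""
    key = unit.lower()
    if key not in _TO_AU:
        raise ValueError(f"unknown unit tag {unit!r}")
    return np.asarray(x, dtype=float) / _TO_AU[key] if np.ndim(x) else float(x) / _TO_AU[key]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    """A file did not conform to the declared dialect."""


class ValidationError(ValueError):
    """A parsed system violates a structural invariant."""


@dataclass
class QMRegion:
    """The quantum subsystem: expansion sites for all multipolar models.

    coords are Angstrom, Z nuclear charges in e, ff_charges optional fixed
    force-field reference charges in e (one per atom).
    """

    elements: list[str]
    coords: np.ndarray
    Z: np.ndarray = None
    ff_charges: np.ndarray | None = None
    net_charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.Z is None:
            try:
                self.Z = np.array([ELEMENT_Z[e] for e in self.elements], dtype=int)
            except KeyError as exc:
                raise ValidationError(f"unknown element symbol {exc.args[0]!r}")
        self.Z = np.asarray(self.Z, dtype=int)
        n = len(self.elements)
        if self.coords.shape != (n, 3) or len(self.Z) != n:
            raise ValidationError(
                f"inconsistent QM region: {n} elements, coords {self.coords.shape}, "
                f"{len(self.Z)} nuclear charges"
            )
        for sym, z in zip(self.elements, self.Z):
            if sym not in ELEMENT_Z:
                raise ValidationError(f"unknown element symbol {sym!r}")
            if ELEMENT_Z[sym] != z:
                raise ValidationError(f"element {sym} does not match Z={z}")
        if self.ff_charges is not None:
            self.ff_charges = np.asarray(self.ff_charges, dtype=float)
            if len(self.ff_charges) != n:
                raise ValidationError("ff_charges must have one entry per QM atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR


@dataclass
class MMCharges:
    """The classical environment: point charges with charge-group labels."""

    coords: np.ndarray
    q: np.ndarray
    group_id: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.q = np.asarray(self.q, dtype=float).reshape(-1)
        self.group_id = np.asarray(self.group_id, dtype=int).reshape(-1)
        if not (len(self.coords) == len(self.q) == len(self.group_id)):
            raise ValidationError("MMCharges fields must have equal lengths")
        if len(self.group_id) and self.group_id.min() < 0:
            raise ValidationError("every MM group_id must be non-negative")

    @property
    def n_charges(self) -> int:
        return len(self.q)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def subset(self, idx) -> "MMCharges":
        idx = np.asarray(idx)
        return MMCharges(self.coords[idx], self.q[idx], self.group_id[idx])

    @staticmethod
    def empty() -> "MMCharges":
        return MMCharges(np.zeros((0, 3)), np.zeros(0), np.zeros(0, dtype=int))


@dataclass
class EnergyReport:
    """Decomposed QM/MM electrostatic energy for one model/scheme/cutoff.

    All components in kcal/mol; ``total = short_range + long_range + mmlc``.
    """

    model: str
    switching: str
    r_off: float
    components: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.components["total"]

    def validate(self, tol: float = 1e-8) -> None:
        c = self.components
        expected = c.get("short_range", 0.0) + c.get("long_range", 0.0) + c.get("mmlc", 0.0)
        if abs(c["total"] - expected) > tol:
            raise ValidationError(
                f"inconsistent EnergyReport: total {c['total']} != sum of parts {expected}"
            )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "switching": self.switching,
            "r_off": self.r_off,
            **self.components,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ---------------------------------------------------------------------------
# xyzq dialect
# ---------------------------------------------------------------------------


def _parse_header(line: str, lineno: int):
    toks = line.split()
    if len(toks) < 2:
        raise ParseError(f"line {lineno}: header must start with '<n_qm> <n_mm>'")
    try:
        n_qm, n_mm = int(toks[0]), int(toks[1])
    except ValueError:
        raise ParseError(f"line {lineno}: header counts must be integers, got {line!r}")
    meta = {"charge": 0, "mult": 1}
    for tok in toks[2:]:
        if "=" not in tok:
            raise ParseError(f"line {lineno}: bad header token {tok!r} (expected key=value)")
        key, val = tok.split("=", 1)
        if key not in meta:
            raise ParseError(f"line {lineno}: unknown header key {key!r}")
        meta[key] = int(val)
    return n_qm, n_mm, meta


def _parse_atom_line(line: str, lineno: int, qm: bool):
    toks = line.split()
    if len(toks) < 5:
        raise ParseError(
            f"line {lineno}: expected 'element x y z q group', missing charge/group column: {line!r}"
        )
    if len(toks) < 6:
        raise ParseError(f"line {lineno}: MM/QM atom lacks a group label: {line!r}")
    sym = toks[0]
    try:
        xyz = [float(t) for t in toks[1:4]]
        q = float(toks[4])
        group = int(toks[5])
    except ValueError:
        raise ParseError(f"line {lineno}: could not parse numeric fields in {line!r}")
    if not qm and group < 0:
        raise ParseError(f"line {lineno}: MM charge has negative group label: {line!r}")
    return sym, xyz, q, group


def _read_frame(lines: list[str], start: int):
    """Parse one frame beginning at index *start*; returns (qm, mm, next_index)."""
    i = start
    while i < len(lines) and (not lines[i].strip() or lines[i].lstrip().startswith("#")):
        i += 1
    if i >= len(lines):
        return None
    n_qm, n_mm, meta = _parse_header(lines[i], i + 1)
    rows = []
    j = i + 1
    while j < len(lines) and len(rows) < n_qm + n_mm:
        if lines[j].strip() and not lines[j].lstrip().startswith("#"):
            rows.append((lines[j], j + 1))
        j += 1
    if len(rows) < n_qm + n_mm:
        raise ParseError(f"frame at line {i + 1}: expected {n_qm + n_mm} atom lines, got {len(rows)}")

    syms, coords, charges = [], [], []
    for line, lineno in rows[:n_qm]:
        sym, xyz, q, _ = _parse_atom_line(line, lineno, qm=True)
        syms.append(sym)
        coords.append(xyz)
        charges.append(q)
    qm = QMRegion(
        elements=syms,
        coords=np.array(coords).reshape(-1, 3) if coords else np.zeros((0, 3)),
        ff_charges=np.array(charges) if charges else None,
        net_charge=meta["charge"],
        multiplicity=meta["mult"],
    )

    mcoords, mq, mgroup = [], [], []
    for line, lineno in rows[n_qm:]:
        _, xyz, q, group = _parse_atom_line(line, lineno, qm=False)
        mcoords.append(xyz)
        mq.append(q)
        mgroup.append(group)
    mm = MMCharges(
        np.array(mcoords).reshape(-1, 3) if mcoords else np.zeros((0, 3)),
        np.array(mq), np.array(mgroup, dtype=int),
    )
    _check_overlap(qm, mm)
    return qm, mm, j


def _check_overlap(qm: QMRegion, mm: MMCharges, tol: float = 1e-6) -> None:
    if qm.n_atoms == 0 or mm.n_charges == 0:
        return
    from scipy.spatial.distance import cdist

    d = cdist(qm.coords, mm.coords)
    if d.min() < tol:
        a, b = np.unravel_index(np.argmin(d), d.shape)
        raise ValidationError(
            f"QM atom {a} and MM charge {b} occupy the same position (QM/MM overlap)"
        )


def load_xyzq(path) -> tuple[QMRegion, MMCharges]:
    """Load the first (usually only) frame of an xyzq file."""
    lines = Path(path).read_text().splitlines()
    out = _read_frame(lines, 0)
    if out is None:
        raise ParseError(f"{path}: empty file")
    return out[0], out[1]


def iter_xyzq_frames(path) -> Iterator[tuple[QMRegion, MMCharges]]:
    """Iterate over all frames of a multi-frame xyzq file."""
    lines = Path(path).read_text().splitlines()
    i = 0
    while True:
        out = _read_frame(lines, i)
        if out is None:
            return
        yield out[0], out[1]
        i = out[2]


def format_xyzq(qm: QMRegion, mm: MMCharges) -> str:
    """Render a system in the xyzq dialect (bit-reproducible formatting)."""
    buf = [f"{qm.n_atoms} {mm.n_charges} charge={qm.net_charge} mult={qm.multiplicity}"]
    ff = qm.ff_charges if qm.ff_charges is not None else np.zeros(qm.n_atoms)
    for sym, xyz, q in zip(qm.elements, qm.coords, ff):
        buf.append(f"{sym:<3s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f} {q:14.10f} -1")
    for xyz, q, g in zip(mm.coords, mm.q, mm.group_id):
        buf.append(f"X   {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f} {q:14.10f} {g:d}")
    return "\n".join(buf) + "\n"


def save_xyzq(path, qm: QMRegion, mm: MMCharges, append: bool = False) -> None:
    """Write a system in the xyzq dialect."""
    with open(path, "a" if append else "w") as fh:
        fh.write(format_xyzq(qm, mm))


# ---------------------------------------------------------------------------
# PDB + companion charge table
# ---------------------------------------------------------------------------


def load_pdb_system(pdb_path, charge_table_path, qm_serials: Sequence[int],
                    qm_net_charge: int = 0, qm_multiplicity: int = 1,
                    qm_ff_charges_from_table: bool = True):
    """Load a QM/MM system from a PDB file plus a two-column charge table.

    The charge table holds ``<atom serial> <charge/e>`` per line.  Atoms whose
    serial appears in *qm_serials* form the QM region (element from the PDB
    element column); every remaining atom becomes an MM point charge with one
    charge group per residue.
    """
    charges = {}
    for lineno, raw in enumerate(Path(charge_table_path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) < 2:
            raise ParseError(f"{charge_table_path} line {lineno}: expected '<serial> <charge>'")
        charges[int(toks[0])] = float(toks[1])

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        u = mda.Universe(str(pdb_path))
    try:
        elements = [e.capitalize() for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        from MDAnalysis.topology.guessers import guess_types

        elements = [e.capitalize() for e in guess_types(u.atoms.names)]

    qm_serials = set(int(s) for s in qm_serials)
    qsyms, qcoords, qff = [], [], []
    mcoords, mq, mgroup = [], [], []
    group_key_to_id: dict[int, int] = {}

    for atom, element in zip(u.atoms, elements):
        serial = int(atom.id)
        if serial not in charges:
            raise ParseError(
                f"{pdb_path}: atom serial {serial} missing from charge table"
            )
        xyz = atom.position.tolist()
        if serial in qm_serials:
            qsyms.append(element)
            qcoords.append(xyz)
            qff.append(charges[serial])
        else:
            key = int(atom.resindex)  # one charge group per residue/molecule
            if key not in group_key_to_id:
                group_key_to_id[key] = len(group_key_to_id)
            mcoords.append(xyz)
            mq.append(charges[serial])
            mgroup.append(group_key_to_id[key])

    qm = QMRegion(
        elements=qsyms, coords=np.array(qcoords).reshape(-1, 3),
        ff_charges=np.array(qff) if (qff and qm_ff_charges_from_table) else None,
        net_charge=qm_net_charge, multiplicity=qm_multiplicity,
    )
    mm = MMCharges(np.array(mcoords).reshape(-1, 3), np.array(mq), np.array(mgroup, dtype=int))
    _check_overlap(qm, mm)
    return qm, mm


# ---------------------------------------------------------------------------
# Run configuration and result tables
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Read a YAML (or JSON — valid YAML) run-configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: run configuration must be a mapping")
    return cfg


def load_system(path, format: str = "xyzq", **kw):
    """Dispatch loader.

    ``xyzq``: the package's own dialect.  ``pdb+charges``: PDB plus a
    companion charge table (needs ``charge_table_path`` and ``qm_serials``
    keyword arguments).  ``config``: a YAML file whose ``system:`` mapping
    names the actual input (keys ``path``, ``format``, and any loader
    keywords), resolved relative to the config file.
    """
    if format == "xyzq":
        return load_xyzq(path)
    if format in ("pdb", "pdb+charges"):
        return load_pdb_system(path, **kw)
    if format == "config":
        cfg = load_config(path)
        sys_cfg = dict(cfg.get("system", {}))
        if "path" not in sys_cfg:
            raise ParseError(f"{path}: config lacks a system.path entry")
        base = Path(path).parent
        target = base / sys_cfg.pop("path")
        fmt = sys_cfg.pop("format", "xyzq")
        if "charge_table_path" in sys_cfg:
            sys_cfg["charge_table_path"] = base / sys_cfg["charge_table_path"]
        return load_system(target, format=fmt, **sys_cfg)
    raise ValueError(f"unknown system format {format!r}")
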