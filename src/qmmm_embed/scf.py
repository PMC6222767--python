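"""Minimal restricted Hartree–Fock / CIS engine with embedding support.

A compact, self-contained Gaussian-basis SCF backend implementing the
:class:`~qmmm_embed.qm_adapter.BackendContract`: one-electron, two-electron
and external point-charge integrals via the McMurchie–Davidson scheme
(Hermite Gaussian expansion + Boys function), restricted Hartree–Fock with
DIIS acceleration, molecular electrostatic potentials on arbitrary point
sets, and singlet vertical excitation energies from configuration
interaction singles (CIS) with the embedding operator contained in the
ground-state Hamiltonian.

The shipped basis is STO-3G for H–F, built from Stewart's universal
three-Gaussian expansions of 1s/2s/2p Slater functions together with the
standard molecular scale factors; the resulting exponents reproduce the
published STO-3G values (e.g. H 1s: 3.42525091, 0.62391373, 0.16885540).
The engine is deliberately small — closed-shell molecules, s/p functions —
which is all the desk-scale benchmark systems require; method and basis are
configuration, not code, so a larger engine can be swapped in behind the
same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammainc, gammaln

from .qm_adapter import (BackendContract, EmbeddingOperatorSpec,
                         SCFConvergenceError)
from .system_io import ANGSTROM_TO_BOHR, HARTREE_IN_EV, MMCharges, QMRegion

# ---------------------------------------------------------------------------
# STO-3G basis data
# ---------------------------------------------------------------------------

# Universal 3-Gaussian least-squares expansions of Slater 1s / 2s / 2p
# functions with unit exponent; scaling a Slater exponent by zeta scales
# every Gaussian exponent by zeta**2.
_EXP_1S = np.array([2.227660584, 0.4057711562, 0.1098175104])
_CF_1S = np.array([0.1543289673, 0.5353281423, 0.4446345422])
_EXP_2SP = np.array([0.9942030370, 0.2310313330, 0.0751386013])
_CF_2S = np.array([-0.0999672292, 0.3995128261, 0.7001154689])
_CF_2P = np.array([0.1559162750, 0.6076837186, 0.3919573931])

# Slater scale factors (zeta) per element: (zeta_1s, zeta_2sp or None)
_STO3G_ZETA = {
    "H": (1.24, None),
    "He": (1.69, None),
    "C": (5.67, 1.72),
    "N": (6.67, 1.95),
    "O": (7.66, 2.25),
    "F": (8.65, 2.55),
}

_CART = {0: [(0, 0, 0)], 1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}


@dataclass
class Shell:
    l: int
    exps: np.ndarray
    coefs: np.ndarray       # contraction coefficients including primitive norms
    center: np.ndarray      # bohr
    atom: int


@dataclass
class BasisSet:
    shells: list
    func_shell: np.ndarray      # shell index of each basis function
    func_cart: list             # (lx, ly, lz) of each basis function
    atom_indices: np.ndarray    # owning atom of each basis function

    @property
    def n_functions(self) -> int:
        return len(self.func_shell)


def _primitive_norm(a: float, l: int) -> float:
    # Cartesian Gaussian norm, valid for l <= 1
    n = (2.0 * a / np.pi) ** 0.75
    if l == 1:
        n *= 2.0 * np.sqrt(a)
    return n


def _contraction_norm(exps, coefs, l: int) -> float:
    p = exps[:, None] + exps[None, :]
    s = (np.pi / p) ** 1.5
    if l == 1:
        s = s / (2.0 * p)
    w = coefs[:, None] * coefs[None, :] * s
    return 1.0 / np.sqrt(w.sum())


def build_basis(qm: QMRegion, name: str = "sto-3g") -> BasisSet:
    if name.lower() != "sto-3g":
        raise ValueError(f"unknown basis {name!r}; this engine ships sto-3g")
    shells = []
    for iatom, (sym, xyz) in enumerate(zip(qm.elements, qm.coords)):
        if sym not in _STO3G_ZETA:
            raise ValueError(f"no STO-3G parameters for element {sym!r} in this engine")
        z1, z2 = _STO3G_ZETA[sym]
        center = np.asarray(xyz, dtype=float) * ANGSTROM_TO_BOHR
        blocks = [(0, _EXP_1S * z1**2, _CF_1S)]
        if z2 is not None:
            blocks.append((0, _EXP_2SP * z2**2, _CF_2S))
            blocks.append((1, _EXP_2SP * z2**2, _CF_2P))
        for l, exps, cf in blocks:
            coefs = cf * np.array([_primitive_norm(a, l) for a in exps])
            coefs = coefs * _contraction_norm(exps, coefs, l)
            shells.append(Shell(l=l, exps=exps, coefs=coefs, center=center, atom=iatom))

    func_shell, func_cart, atom_indices = [], [], []
    for si, sh in enumerate(shells):
        for cart in _CART[sh.l]:
            func_shell.append(si)
            func_cart.append(cart)
            atom_indices.append(sh.atom)
    return BasisSet(shells=shells, func_shell=np.array(func_shell),
                    func_cart=func_cart, atom_indices=np.array(atom_indices))


# ---------------------------------------------------------------------------
# McMurchie–Davidson primitives
# ---------------------------------------------------------------------------


def boys(nmax: int, x) -> np.ndarray:
    """Boys functions F_0..F_nmax; x may be scalar or array."""
    x = np.asarray(x, dtype=float)
    out = np.empty((nmax + 1,) + x.shape)
    small = x < 1e-13
    xs = np.where(small, 1.0, x)
    for n in range(nmax + 1):
        a = n + 0.5
        fn = 0.5 * np.exp(gammaln(a)) * gammainc(a, xs) / xs**a
        out[n] = np.where(small, 1.0 / (2 * n + 1) - x / (2 * n + 3), fn)
    return out


def hermite_E(la: int, lb: int, a: float, b: float, AB: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one dimension."""
    p = a + b
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = np.exp(-a * b / p * AB * AB)
    PA = -b * AB / p
    PB = a * AB / p
    for i in range(1, la + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t]
            if t > 0:
                v += E[i - 1, 0, t - 1] / (2 * p)
            if t + 1 <= i - 1:
                v += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = v
    for j in range(1, lb + 1):
        for i in range(la + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t]
                if t > 0:
                    v += E[i, j - 1, t - 1] / (2 * p)
                if t + 1 <= i + j - 1:
                    v += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = v
    return E


def hermite_R(tmax: int, umax: int, vmax: int, p: float, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R_{t,u,v}(p, PC); PC shape (..., 3).

    Returns array of shape (tmax+1, umax+1, vmax+1) + PC.shape[:-1].
    """
    PC = np.asarray(PC, dtype=float)
    X, Y, Z = PC[..., 0], PC[..., 1], PC[..., 2]
    nmax = tmax + umax + vmax
    F = boys(nmax, p * (X * X + Y * Y + Z * Z))
    cache: dict = {}

    def R(n, t, u, v):
        key = (n, t, u, v)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = (-2.0 * p) ** n * F[n]
        elif t > 0:
            val = X * R(n + 1, t - 1, u, v)
            if t > 1:
                val = val + (t - 1) * R(n + 1, t - 2, u, v)
        elif u > 0:
            val = Y * R(n + 1, t, u - 1, v)
            if u > 1:
                val = val + (u - 1) * R(n + 1, t, u - 2, v)
        else:
            val = Z * R(n + 1, t, u, v - 1)
            if v > 1:
                val = val + (v - 1) * R(n + 1, t, u, v - 2)
        cache[key] = val
        return val

    out = np.empty((tmax + 1, umax + 1, vmax + 1) + X.shape)
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                out[t, u, v] = R(0, t, u, v)
    return out


# ---------------------------------------------------------------------------
# Integral engine (one fixed geometry/basis)
# ---------------------------------------------------------------------------


class IntegralEngine:
    """Integral factory for one basis set, with shell-pair caching.

    Basis functions are enumerated in shell order, so restricting loops to
    fa >= fb guarantees shell(fa) >= shell(fb) and stored shell pairs are
    used as-is.
    """

    def __init__(self, basis: BasisSet):
        self.basis = basis
        self.n = basis.n_functions
        self._pairs = {}
        shells = basis.shells
        for i, sa in enumerate(shells):
            for j in range(i + 1):
                sb = shells[j]
                prims = []
                for a, ca in zip(sa.exps, sa.coefs):
                    for b, cb in zip(sb.exps, sb.coefs):
                        p = a + b
                        P = (a * sa.center + b * sb.center) / p
                        # two extra angular slots on the ket support moment
                        # and kinetic integrals
                        Es = [hermite_E(sa.l, sb.l + 2, a, b,
                                        sa.center[d] - sb.center[d]) for d in range(3)]
                        prims.append((ca * cb, a, b, p, P, Es))
                self._pairs[(i, j)] = prims
        self._funcs = [(basis.func_shell[f], basis.func_cart[f])
                       for f in range(self.n)]

    # -- one-electron -------------------------------------------------------

    def overlap_kinetic_moment(self):
        """Returns (S, T, M) with M[k] = <mu| r_k |nu> about the origin (bohr)."""
        n = self.n
        S = np.zeros((n, n))
        T = np.zeros((n, n))
        M = np.zeros((3, n, n))
        for fa in range(n):
            ia, la = self._funcs[fa]
            for fb in range(fa + 1):
                ib, lb = self._funcs[fb]
                B = self.basis.shells[ib].center
                s_val = t_val = 0.0
                m_val = np.zeros(3)
                for c, a, b, p, P, Es in self._pairs[(ia, ib)]:
                    pref = np.sqrt(np.pi / p)
                    S1 = [Es[d][:, :, 0] * pref for d in range(3)]
                    sx = [S1[d][la[d], lb[d]] for d in range(3)]
                    s_val += c * sx[0] * sx[1] * sx[2]
                    kin = 0.0
                    for d in range(3):
                        j = lb[d]
                        kd = b * (2 * j + 1) * S1[d][la[d], j] \
                            - 2.0 * b * b * S1[d][la[d], j + 2]
                        if j >= 2:
                            kd -= 0.5 * j * (j - 1) * S1[d][la[d], j - 2]
                        others = [sx[e] for e in range(3) if e != d]
                        kin += kd * others[0] * others[1]
                    t_val += c * kin
                    for d in range(3):
                        mom_d = S1[d][la[d], lb[d] + 1] + B[d] * S1[d][la[d], lb[d]]
                        others = [sx[e] for e in range(3) if e != d]
                        m_val[d] += c * mom_d * others[0] * others[1]
                S[fa, fb] = S[fb, fa] = s_val
                T[fa, fb] = T[fb, fa] = t_val
                for d in range(3):
                    M[d, fa, fb] = M[d, fb, fa] = m_val[d]
        return S, T, M

    # -- external point charges ---------------------------------------------

    def point_charge_operator(self, points_bohr: np.ndarray,
                              charges: np.ndarray | None = None):
        """Coulomb integrals A_c[mu,nu] = <mu| 1/|r - C_c| |nu>.

        With *charges* given, returns the contracted matrix sum_c q_c A_c
        (positive-kernel convention; the electronic term of the Hamiltonian
        is the negative of this).  Without charges, returns the full
        (n_points, n, n) stack.
        """
        n = self.n
        pts = np.atleast_2d(points_bohr)
        contract = charges is not None
        out = np.zeros((n, n)) if contract else np.zeros((len(pts), n, n))
        for fa in range(n):
            ia, la = self._funcs[fa]
            for fb in range(fa + 1):
                ib, lb = self._funcs[fb]
                acc = 0.0 if contract else np.zeros(len(pts))
                for c, a, b, p, P, Es in self._pairs[(ia, ib)]:
                    tmax, umax, vmax = (la[0] + lb[0], la[1] + lb[1], la[2] + lb[2])
                    R = hermite_R(tmax, umax, vmax, p, P[None, :] - pts)
                    val = np.zeros(len(pts))
                    for t in range(tmax + 1):
                        et = Es[0][la[0], lb[0], t]
                        if et == 0.0:
                            continue
                        for u in range(umax + 1):
                            eu = Es[1][la[1], lb[1], u]
                            if eu == 0.0:
                                continue
                            for v in range(vmax + 1):
                                ev = Es[2][la[2], lb[2], v]
                                if ev == 0.0:
                                    continue
                                val += et * eu * ev * R[t, u, v]
                    acc = acc + c * (2.0 * np.pi / p) * ((val @ charges) if contract else val)
                if contract:
                    out[fa, fb] = out[fb, fa] = acc
                else:
                    out[:, fa, fb] = out[:, fb, fa] = acc
        return out

    # -- two-electron -------------------------------------------------------

    def eri(self) -> np.ndarray:
        """Full (mu nu | la si) tensor in chemists' notation (8-fold symmetry)."""
        n = self.n
        G = np.zeros((n, n, n, n))
        done = np.zeros((n, n, n, n), dtype=bool)
        for fa in range(n):
            ia, la = self._funcs[fa]
            for fb in range(fa + 1):
                ib, lb = self._funcs[fb]
                prims1 = self._pairs[(ia, ib)]
                t1 = (la[0] + lb[0], la[1] + lb[1], la[2] + lb[2])
                for fc in range(fa + 1):
                    ic, lc = self._funcs[fc]
                    fd_max = fb if fc == fa else fc
                    for fd in range(fd_max + 1):
                        if done[fa, fb, fc, fd]:
                            continue
                        id_, ld = self._funcs[fd]
                        prims2 = self._pairs[(ic, id_)]
                        t2 = (lc[0] + ld[0], lc[1] + ld[1], lc[2] + ld[2])
                        val = 0.0
                        for c1, a1, b1, p, P, E1 in prims1:
                            e1x = E1[0][la[0], lb[0], :t1[0] + 1]
                            e1y = E1[1][la[1], lb[1], :t1[1] + 1]
                            e1z = E1[2][la[2], lb[2], :t1[2] + 1]
                            for c2, a2, b2, q, Q, E2 in prims2:
                                alpha = p * q / (p + q)
                                R = hermite_R(t1[0] + t2[0], t1[1] + t2[1],
                                              t1[2] + t2[2], alpha, P - Q)
                                e2x = E2[0][lc[0], ld[0], :t2[0] + 1]
                                e2y = E2[1][lc[1], ld[1], :t2[1] + 1]
                                e2z = E2[2][lc[2], ld[2], :t2[2] + 1]
                                acc = 0.0
                                for t in range(t1[0] + 1):
                                    if e1x[t] == 0.0:
                                        continue
                                    for u in range(t1[1] + 1):
                                        if e1y[u] == 0.0:
                                            continue
                                        for v in range(t1[2] + 1):
                                            if e1z[v] == 0.0:
                                                continue
                                            e1 = e1x[t] * e1y[u] * e1z[v]
                                            for tt in range(t2[0] + 1):
                                                if e2x[tt] == 0.0:
                                                    continue
                                                for uu in range(t2[1] + 1):
                                                    if e2y[uu] == 0.0:
                                                        continue
                                                    for vv in range(t2[2] + 1):
                                                        if e2z[vv] == 0.0:
                                                            continue
                                                        sign = -1.0 if (tt + uu + vv) % 2 else 1.0
                                                        acc += e1 * e2x[tt] * e2y[uu] * e2z[vv] \
                                                            * sign * R[t + tt, u + uu, v + vv]
                                val += c1 * c2 * acc * 2.0 * np.pi**2.5 / \
                                    (p * q * np.sqrt(p + q))
                        for idx in _eri_perms(fa, fb, fc, fd):
                            G[idx] = val
                            done[idx] = True
        return G


def _eri_perms(a, b, c, d):
    return {(a, b, c, d), (b, a, c, d), (a, b, d, c), (b, a, d, c),
            (c, d, a, b), (d, c, a, b), (c, d, b, a), (d, c, b, a)}


# ---------------------------------------------------------------------------
# RHF backend
# ---------------------------------------------------------------------------


@dataclass
class RHFDensity:
    """Converged one-particle density with the matrices the multipole and
    population machinery needs (Tr(D S) equals the electron count)."""

    backend: "HartreeFockBackend"
    density_matrix: np.ndarray      # spin-summed AO density D
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    overlap: np.ndarray
    moment_integrals: np.ndarray    # (3, n, n), <mu| r_k |nu> in bohr
    basis_atom_indices: np.ndarray
    n_electrons: int
    geometry_tag: str
    e_total: float


class _GeometryCache:
    def __init__(self, basis: BasisSet, tag: str):
        self.basis = basis
        self.tag = tag
        self.engine = IntegralEngine(basis)
        self.S, self.T, self.M = self.engine.overlap_kinetic_moment()
        self.G = self.engine.eri()
        s_eval, s_evec = np.linalg.eigh(self.S)
        if s_eval.min() < 1e-10:
            raise RuntimeError("linearly dependent basis (overlap not invertible)")
        self.X = s_evec @ np.diag(s_eval**-0.5) @ s_evec.T


class HartreeFockBackend(BackendContract):
    """Restricted Hartree–Fock / CIS engine satisfying the backend contract."""

    capabilities = {
        "scf": True, "esp_on_points": True,
        "density_charge_interaction": True, "tddft": True,
    }

    def __init__(self, basis: str = "sto-3g", conv_tol: float = 1e-10,
                 max_cycles: int = 200, diis_size: int = 8):
        self.basis_name = basis
        self.conv_tol = conv_tol
        self.max_cycles = max_cycles
        self.diis_size = diis_size
        self._cache: dict[str, _GeometryCache] = {}

    # -- helpers ------------------------------------------------------------

    def _geometry(self, qm: QMRegion) -> _GeometryCache:
        tag = self.basis_name + "|" + "|".join(
            f"{s}{x:.9f},{y:.9f},{z:.9f}" for s, (x, y, z) in zip(qm.elements, qm.coords)
        )
        if tag not in self._cache:
            self._cache[tag] = _GeometryCache(build_basis(qm, self.basis_name), tag)
        return self._cache[tag]

    @staticmethod
    def _n_electrons(qm: QMRegion) -> int:
        n = int(qm.Z.sum()) - qm.net_charge
        if qm.multiplicity != 1 or n % 2:
            raise ValueError("this engine is restricted closed-shell (even N, singlet)")
        return n

    def _external_terms(self, qm: QMRegion, geo: _GeometryCache,
                        operator: EmbeddingOperatorSpec):
        """(h_ext, e_nuc_ext): electronic matrix and nuclear/external energy."""
        h_ext = np.zeros((geo.basis.n_functions,) * 2)
        e_nuc_ext = operator.nuclear_energy_shift
        if operator.n_charges:
            pts = operator.charge_coords * ANGSTROM_TO_BOHR
            h_ext -= geo.engine.point_charge_operator(pts, operator.charge_values)
            d = cdist(qm.coords_bohr, pts)
            if d.min() < 1e-6:
                raise ValueError("external charge sits on a nucleus")
            e_nuc_ext += float(qm.Z @ (1.0 / d) @ operator.charge_values)
        if operator.one_electron_matrix is not None:
            h_ext += operator.one_electron_matrix
        return h_ext, e_nuc_ext

    @staticmethod
    def _nuclear_repulsion(qm: QMRegion) -> float:
        if qm.n_atoms < 2:
            return 0.0
        d = cdist(qm.coords_bohr, qm.coords_bohr)
        iu = np.triu_indices(qm.n_atoms, 1)
        return float(np.sum(np.outer(qm.Z, qm.Z)[iu] / d[iu]))

    def _fock(self, geo: _GeometryCache, h: np.ndarray, D: np.ndarray) -> np.ndarray:
        J = np.einsum("mnls,ls->mn", geo.G, D)
        K = np.einsum("mlns,ls->mn", geo.G, D)
        return h + J - 0.5 * K

    @staticmethod
    def _density_from_fock(F, X, n_occ):
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        Cocc = C[:, :n_occ]
        return 2.0 * Cocc @ Cocc.T, C, e

    # -- contract implementation --------------------------------------------

    def converged_scf(self, qm: QMRegion, operator: EmbeddingOperatorSpec | None = None,
                      initial: RHFDensity | None = None):
        """Converge the SCF under the embedding operator.

        Returns ``(density, energy_first_cycle, energy_converged)`` in
        hartree; the first-cycle energy is that of the initial density
        (provided handle, or core guess) evaluated under the operator.
        """
        operator = operator or EmbeddingOperatorSpec.vacuum()
        geo = self._geometry(qm)
        n_occ = self._n_electrons(qm) // 2
        h = geo.T - geo.engine.point_charge_operator(qm.coords_bohr, qm.Z.astype(float))
        h_ext, e_nuc_ext = self._external_terms(qm, geo, operator)
        h = h + h_ext
        e_const = self._nuclear_repulsion(qm) + e_nuc_ext

        if initial is not None:
            D = np.asarray(initial.density_matrix)
        else:
            D, _, _ = self._density_from_fock(h, geo.X, n_occ)

        def total_energy(D, F):
            return 0.5 * np.einsum("mn,mn->", D, h + F) + e_const

        F = self._fock(geo, h, D)
        e_first = total_energy(D, F)
        e_prev = e_first

        fock_list, err_list = [], []
        converged = False
        for cycle in range(1, self.max_cycles + 1):
            err = F @ D @ geo.S - geo.S @ D @ F
            fock_list.append(F)
            err_list.append(err)
            if len(fock_list) > self.diis_size:
                fock_list.pop(0)
                err_list.pop(0)
            if len(fock_list) > 1:
                m = len(fock_list)
                B = -np.ones((m + 1, m + 1))
                B[m, m] = 0.0
                for i in range(m):
                    for j in range(m):
                        B[i, j] = np.einsum("mn,mn->", err_list[i], err_list[j])
                rhs = np.zeros(m + 1)
                rhs[m] = -1.0
                try:
                    w = np.linalg.solve(B, rhs)[:m]
                    F = sum(wi * Fi for wi, Fi in zip(w, fock_list))
                except np.linalg.LinAlgError:
                    pass
            D, C, eps = self._density_from_fock(F, geo.X, n_occ)
            F = self._fock(geo, h, D)
            e_curr = total_energy(D, F)
            if abs(e_curr - e_prev) < self.conv_tol and np.abs(err).max() < 1e-7:
                converged = True
                break
            e_prev = e_curr
        if not converged:
            raise SCFConvergenceError(
                f"SCF failed to converge in {self.max_cycles} cycles", self.max_cycles)

        density = RHFDensity(
            backend=self, density_matrix=D, mo_coeff=C, mo_energy=eps,
            overlap=geo.S, moment_integrals=geo.M,
            basis_atom_indices=geo.basis.atom_indices,
            n_electrons=2 * n_occ, geometry_tag=geo.tag, e_total=e_curr,
        )
        return density, e_first, e_curr

    def esp_on_points(self, density: RHFDensity, qm: QMRegion,
                      points: np.ndarray) -> np.ndarray:
        """Molecular ESP (a.u.): nuclear plus electronic contributions.
        *points* in Angstrom."""
        geo = self._geometry(qm)
        pts_b = np.atleast_2d(np.asarray(points, dtype=float)) * ANGSTROM_TO_BOHR
        d = cdist(pts_b, qm.coords_bohr)
        if d.min() < 1e-6:
            raise ValueError("ESP requested on top of a nucleus")
        phi_nuc = (1.0 / d) @ qm.Z
        D = density.density_matrix
        phi = np.empty(len(pts_b))
        chunk = 512
        for i in range(0, len(pts_b), chunk):
            A = geo.engine.point_charge_operator(pts_b[i:i + chunk])
            phi[i:i + chunk] = phi_nuc[i:i + chunk] - np.einsum("cmn,mn->c", A, D)
        return phi

    def density_charge_interaction(self, density: RHFDensity, qm: QMRegion,
                                   charges: MMCharges) -> float:
        """Coulomb energy (hartree) between the QM density+nuclei and a set
        of external point charges."""
        if charges.n_charges == 0:
            return 0.0
        geo = self._geometry(qm)
        pts_b = charges.coords_bohr
        d = cdist(qm.coords_bohr, pts_b)
        if d.min() < 1e-6:
            raise ValueError("MM charge coincides with a QM nucleus")
        e_nuc = float(qm.Z @ (1.0 / d) @ charges.q)
        V = geo.engine.point_charge_operator(pts_b, charges.q)
        return e_nuc - float(np.einsum("mn,mn->", V, density.density_matrix))

    def excitation_energies(self, density: RHFDensity, qm: QMRegion,
                            operator: EmbeddingOperatorSpec | None = None,
                            n_states: int = 1) -> np.ndarray:
        """Lowest singlet CIS excitation energies (eV) on top of the SCF
        solution carried by *density* (which must have been converged under
        the same embedding operator; the operator itself enters only through
        the ground-state orbitals since all embedding terms here are static
        one-electron potentials)."""
        self.require("tddft")
        geo = self._geometry(qm)
        if density.geometry_tag != geo.tag:
            raise ValueError("density belongs to a different geometry/basis")
        C, eps = density.mo_coeff, density.mo_energy
        n_occ = density.n_electrons // 2
        n_virt = geo.basis.n_functions - n_occ
        if n_virt == 0:
            raise ValueError("no virtual orbitals: cannot compute excitations")
        mo_eri = np.einsum("mnls,mi,nj,lk,st->ijkt", geo.G, C, C, C, C, optimize=True)
        o = slice(0, n_occ)
        v = slice(n_occ, None)
        ov = mo_eri[o, v, o, v]        # (ia|jb)
        oo_vv = mo_eri[o, o, v, v]     # (ij|ab)
        de = eps[v][None, :] - eps[o][:, None]
        dim = n_occ * n_virt
        A = np.zeros((dim, dim))
        A += np.diag(de.ravel())
        A += 2.0 * ov.transpose(0, 1, 2, 3).reshape(dim, dim)
        A -= oo_vv.transpose(0, 2, 1, 3).reshape(dim, dim)
        w = np.linalg.eigvalsh(0.5 * (A + A.T))
        return w[:n_states] * HARTREE_IN_EV
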