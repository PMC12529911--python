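"""Closed-shell MP2: spin components, unrelaxed and relaxed densities.

Amplitudes are stored as ``t2[i,j,a,b] = (ia|jb) / (e_i + e_j - e_a - e_b)``
over canonical RHF orbitals.  The opposite-spin and same-spin energy
components are

    E_OS = sum t2[i,j,a,b] (ia|jb)
    E_SS = sum (t2[i,j,a,b] - t2[i,j,b,a]) (ia|jb)

The unrelaxed one-particle density adds the amplitude-quadratic occupied-
occupied and virtual-virtual corrections to the HF density; its eigenvalues
(natural occupancies) lie strictly in [0, 1] per spin.  The relaxed density
additionally carries the occupied-virtual orbital-response block from the
Z-vector (CPHF) equations, and the relaxed two-particle density is assembled
from a separable part (linear in the relaxed correction) plus the amplitude
cumulant, such that contracting with (h, (pq|rs)) reproduces the MP2 total
energy exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .rdm import OneRdm, TwoRdm, hf_rdm1
from .scf import ScfSolution

__all__ = ["Mp2Components", "mp2_components", "unrelaxed_rdm1",
           "unrelaxed_occupancies", "relaxed_densities", "mo_eri",
           "DegenerateInputError", "DensityConstructionError"]


class DegenerateInputError(ValueError):
    pass


class DensityConstructionError(RuntimeError):
    pass


@dataclasses.dataclass
class Mp2Components:
    """Spin-resolved MP2 correlation energy and amplitudes."""

    e_os: float
    e_ss: float
    t2: np.ndarray          # (nocc_act, nocc_act, nvir, nvir)
    frozen_core: bool
    n_frozen: int
    scf: ScfSolution

    @property
    def e_corr(self) -> float:
        return self.e_os + self.e_ss

    @property
    def t2_tilde(self) -> np.ndarray:
        """2 t2 - t2 with the virtuals swapped (spin-adapted contraction)."""
        return 2.0 * self.t2 - self.t2.transpose(0, 1, 3, 2)


def mo_eri(scf: ScfSolution) -> np.ndarray:
    """Full MO-basis (pq|rs) tensor."""
    c = scf.orbital_coefficients
    return np.einsum("pi,qj,rk,sl,pqrs->ijkl", c, c, c, c, scf.integrals.eri,
                     optimize=True)


def _n_core(molecule) -> int:
    """Frozen-core count: one 1s pair per non-hydrogen/helium atom."""
    return sum(1 for el in molecule.atoms if el not in ("H", "He"))


def mp2_components(scf: ScfSolution, frozen_core: bool = False) -> Mp2Components:
    """Opposite- and same-spin MP2 correlation components.

    Raises ``DegenerateInputError`` when there is no virtual space.
    """
    nocc, nbf = scf.n_occupied, scf.n_basis
    nvir = nbf - nocc
    if nvir == 0:
        raise DegenerateInputError("no virtual orbitals: MP2 undefined")
    nfro = _n_core(scf.molecule) if frozen_core else 0
    c = scf.orbital_coefficients
    eps = scf.orbital_energies
    g = scf.integrals.eri
    c_occ = c[:, nfro:nocc]
    c_vir = c[:, nocc:]
    ovov = np.einsum("pi,qa,rj,sb,pqrs->iajb", c_occ, c_vir, c_occ, c_vir, g,
                     optimize=True)
    e_o = eps[nfro:nocc]
    e_v = eps[nocc:]
    denom = (e_o[:, None, None, None] + e_o[None, :, None, None]
             - e_v[None, None, :, None] - e_v[None, None, None, :])
    giajb = ovov.transpose(0, 2, 1, 3)          # (i, j, a, b)
    t2 = giajb / denom
    e_os = float(np.einsum("ijab,ijab->", t2, giajb))
    e_ss = float(np.einsum("ijab,ijab->", t2 - t2.transpose(0, 1, 3, 2), giajb))
    return Mp2Components(e_os, e_ss, t2, frozen_core, nfro, scf)


def _correction_blocks(mp2: Mp2Components) -> tuple[np.ndarray, np.ndarray]:
    """Spin-summed amplitude-quadratic oo and vv density corrections."""
    t2, tt = mp2.t2, mp2.t2_tilde
    p_oo = -2.0 * np.einsum("ikab,jkab->ij", t2, tt, optimize=True)
    p_vv = 2.0 * np.einsum("ijac,ijbc->ab", t2, tt, optimize=True)
    return p_oo, p_vv


def unrelaxed_rdm1(scf: ScfSolution, mp2: Mp2Components) -> OneRdm:
    """MP2 first-order unrelaxed one-particle density (per spin, MO basis)."""
    nocc, nbf = scf.n_occupied, scf.n_basis
    nfro = mp2.n_frozen
    p_oo, p_vv = _correction_blocks(mp2)
    d = hf_rdm1(nocc, nbf).alpha
    d[nfro:nocc, nfro:nocc] += 0.5 * p_oo
    d[nocc:, nocc:] += 0.5 * p_vv
    return OneRdm(d, d.copy(), kind="MP2-unrelaxed")


def unrelaxed_occupancies(scf: ScfSolution, mp2: Mp2Components,
                          clamp_tol: float = 1e-8):
    """Natural occupancies of the unrelaxed MP2 density, per spin.

    Eigenvalues are clamped to [0, 1] within ``clamp_tol``; violations beyond
    it raise ``DensityConstructionError``.  Returns an
    :class:`~cdscs.indices.OccupancySpectrum`.
    """
    from .indices import OccupancySpectrum

    d = unrelaxed_rdm1(scf, mp2)
    occ_per_spin = []
    for mat in (d.alpha, d.beta):
        vals = np.linalg.eigvalsh(mat)[::-1]
        if vals.min() < -clamp_tol or vals.max() > 1.0 + clamp_tol:
            raise DensityConstructionError(
                f"natural occupancy outside [0,1] by more than {clamp_tol:g}: "
                f"[{vals.min():.3e}, {vals.max():.6f}]")
        occ_per_spin.append(np.clip(vals, 0.0, 1.0))
    return OccupancySpectrum(alpha=occ_per_spin[0], beta=occ_per_spin[1],
                             n_electrons=scf.molecule.n_electrons)


def _zvector(scf: ScfSolution, mp2: Mp2Components, g_mo: np.ndarray,
             p_oo: np.ndarray, p_vv: np.ndarray,
             tol: float = 1e-10) -> np.ndarray:
    """Solve the CPHF (Z-vector) equations for the occupied-virtual response.

    Returns the spin-summed ov block z[a, i].  Dense solve; the orbital
    Hessian for the systems in scope is tiny.
    """
    if mp2.n_frozen:
        raise DensityConstructionError(
            "relaxed densities are implemented for all-electron MP2 only")
    nocc, nbf = scf.n_occupied, scf.n_basis
    nvir = nbf - nocc
    eps = scf.orbital_energies
    o = slice(0, nocc)
    v = slice(nocc, nbf)
    t2, tt = mp2.t2, mp2.t2_tilde

    g_ovov = g_mo[o, v, o, v]
    g_vvov = g_mo[v, v, o, v]
    g_ooov = g_mo[o, o, o, v]
    # amplitude part of the Lagrangian: derivative of E(2) through the
    # explicit MO dependence of (ia|jb)
    l_amp = (4.0 * np.einsum("ijcb,acjb->ai", tt, g_vvov, optimize=True)
             - 4.0 * np.einsum("kjab,kijb->ai", tt, g_ooov, optimize=True))
    # Fock-response part: unrelaxed oo/vv blocks against the CPHF supermatrix
    def resp(pmat, block_pq):
        """sum_pq P_pq [4(ai|pq) - (ap|iq) - (aq|ip)] over the given MO block."""
        g_aipq = g_mo[v, o, block_pq, block_pq]
        g_apiq = g_mo[v, block_pq, o, block_pq]
        return (4.0 * np.einsum("pq,aipq->ai", pmat, g_aipq, optimize=True)
                - np.einsum("pq,apiq->ai", pmat, g_apiq, optimize=True)
                - np.einsum("pq,aqip->ai", pmat, g_apiq, optimize=True))

    l_fock = resp(p_oo, o) + resp(p_vv, v)
    l_total = l_amp + l_fock

    # singlet orbital Hessian A_{ai,bj}
    e_vo = eps[v][:, None] - eps[o][None, :]
    a_mat = (np.einsum("ai,ab,ij->aibj", e_vo, np.eye(nvir), np.eye(nocc),
                       optimize=True)
             + 4.0 * g_mo[v, o, v, o]
             - np.einsum("abij->aibj", g_mo[v, v, o, o])
             - np.einsum("ajib->aibj", g_mo[v, o, o, v]))
    a2 = a_mat.reshape(nvir * nocc, nvir * nocc)
    # factor 1/2: the Lagrangian above is assembled in the spin-summed
    # convention while A is the per-spin singlet Hessian
    z = 0.5 * np.linalg.solve(a2, -l_total.reshape(-1))
    return z.reshape(nvir, nocc)


def relaxed_densities(scf: ScfSolution, mp2: Mp2Components,
                      g_mo: np.ndarray | None = None) -> tuple[OneRdm, TwoRdm]:
    """Relaxed MP2 one- and two-particle densities (MO basis, per spin).

    The one-particle density includes the Z-vector orbital response; the
    two-particle density is separable part (linear in the correction) plus
    the amplitude cumulant.  In the zero-amplitude limit both collapse to
    the HF densities.
    """
    if g_mo is None:
        g_mo = mo_eri(scf)
    nocc, nbf = scf.n_occupied, scf.n_basis
    o = slice(0, nocc)
    v = slice(nocc, nbf)
    p_oo, p_vv = _correction_blocks(mp2)
    z = _zvector(scf, mp2, g_mo, p_oo, p_vv)

    delta = np.zeros((nbf, nbf))            # spin-summed relaxed correction
    delta[o, o] = p_oo
    delta[v, v] = p_vv
    delta[v, o] = z
    delta[o, v] = z.T

    d_hf = hf_rdm1(nocc, nbf)
    d_spin = d_hf.alpha + 0.5 * delta
    rdm1 = OneRdm(d_spin, d_spin.copy(), kind="MP2-relaxed")

    # separable part per spin block, linear in the per-spin correction
    d0 = d_hf.alpha
    dd = 0.5 * delta
    coul0 = np.einsum("pq,rs->pqrs", d0, d0)
    exch0 = np.einsum("ps,rq->pqrs", d0, d0)
    coul1 = (np.einsum("pq,rs->pqrs", d0, dd) + np.einsum("pq,rs->pqrs", dd, d0))
    exch1 = (np.einsum("ps,rq->pqrs", d0, dd) + np.einsum("ps,rq->pqrs", dd, d0))
    gamma_ss = coul0 - exch0 + coul1 - exch1
    gamma_ab = coul0 + coul1

    # amplitude cumulant: OS block carries plain amplitudes, SS the
    # antisymmetrized ones; both enter twice (bra and ket first order)
    t2 = mp2.t2
    t_anti = t2 - t2.transpose(0, 1, 3, 2)
    cum_ab = np.zeros((nbf,) * 4)
    cum_ss = np.zeros((nbf,) * 4)
    cum_ab[o, v, o, v] = np.einsum("ijab->iajb", t2)
    cum_ab[v, o, v, o] = np.einsum("ijab->aibj", t2)
    cum_ss[o, v, o, v] = np.einsum("ijab->iajb", t_anti)
    cum_ss[v, o, v, o] = np.einsum("ijab->aibj", t_anti)

    rdm2 = TwoRdm(aa=gamma_ss + cum_ss, bb=gamma_ss + cum_ss.copy(),
                  ab=gamma_ab + cum_ab, kind="MP2-relaxed")
    return rdm1, rdm2


def unrelaxed_rdm2(scf: ScfSolution, mp2: Mp2Components,
                   g_mo: np.ndarray | None = None) -> TwoRdm:
    """Two-particle density with the unrelaxed (amplitude-only) correction."""
    nocc, nbf = scf.n_occupied, scf.n_basis
    o = slice(0, nocc)
    v = slice(nocc, nbf)
    p_oo, p_vv = _correction_blocks(mp2)
    delta = np.zeros((nbf, nbf))
    delta[o, o] = p_oo
    delta[v, v] = p_vv
    d0 = hf_rdm1(nocc, nbf).alpha
    dd = 0.5 * delta
    coul = (np.einsum("pq,rs->pqrs", d0, d0)
            + np.einsum("pq,rs->pqrs", d0, dd) + np.einsum("pq,rs->pqrs", dd, d0))
    exch = (np.einsum("ps,rq->pqrs", d0, d0)
            + np.einsum("ps,rq->pqrs", d0, dd) + np.einsum("ps,rq->pqrs", dd, d0))
    t2 = mp2.t2
    t_anti = t2 - t2.transpose(0, 1, 3, 2)
    cum_ab = np.zeros((nbf,) * 4)
    cum_ss = np.zeros((nbf,) * 4)
    cum_ab[o, v, o, v] = np.einsum("ijab->iajb", t2)
    cum_ab[v, o, v, o] = np.einsum("ijab->aibj", t2)
    cum_ss[o, v, o, v] = np.einsum("ijab->iajb", t_anti)
    cum_ss[v, o, v, o] = np.einsum("ijab->aibj", t_anti)
    return TwoRdm(aa=coul - exch + cum_ss, bb=coul - exch + cum_ss.copy(),
                  ab=coul + cum_ab, kind="MP2-unrelaxed")
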