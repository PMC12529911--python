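"""Full configuration interaction for few-electron closed-shell systems.

Scope is deliberately small (up to 4 electrons: H2, He, He2, LiH) -- enough
to generate exact Coulomb-hole references.  Two paths:

* two-electron singlets: dense CI in the spatial pair basis |p_a q_b>,
  H_{pq,rs} = h_pr d_qs + h_qs d_pr + (pr|qs);
* the general case: determinant CI driven by single-replacement (string)
  lists, with the ground state from a Davidson-type iterative solve.

Spin-blocked two-particle densities follow the conventions of
:mod:`cdscs.rdm`.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse.linalg as spla

from .mp2 import mo_eri
from .rdm import OneRdm, TwoRdm
from .scf import ScfSolution, UnsupportedSystemError

__all__ = ["FciResult", "fci_solve"]

MAX_ELECTRONS = 4


class FciResult:
    def __init__(self, energy: float, rdm1: OneRdm, rdm2: TwoRdm,
                 e_corr: float):
        self.energy = energy
        self.rdm1 = rdm1
        self.rdm2 = rdm2
        self.e_corr = e_corr


def _pair_ci(h: np.ndarray, g: np.ndarray, e_nuc: float):
    """Dense FCI for a two-electron singlet in the |p_alpha q_beta> basis."""
    n = h.shape[0]
    ham = (np.einsum("pr,qs->pqrs", h, np.eye(n))
           + np.einsum("qs,pr->pqrs", h, np.eye(n))
           + g.transpose(0, 2, 1, 3))            # (pr|qs) -> [pq,rs]
    ham = ham.reshape(n * n, n * n)
    # singlet ground state: the symmetric sector; full diagonalization of the
    # pair matrix is fine at these sizes, but eigsh is cheaper for big bases
    if n * n <= 400:
        w, v = np.linalg.eigh(ham)
        e0, c = w[0], v[:, 0]
    else:
        w, v = spla.eigsh(ham, k=1, which="SA")
        e0, c = w[0], v[:, 0]
    cmat = c.reshape(n, n)
    # enforce the symmetric (singlet) form; antisymmetric ground states would
    # be triplets and cannot happen for a closed-shell Hamiltonian minimum
    cmat = 0.5 * (cmat + cmat.T)
    cmat /= np.linalg.norm(cmat)
    gamma_ab = np.einsum("pr,qs->pqrs", cmat, cmat)
    zeros = np.zeros_like(gamma_ab)
    rdm2 = TwoRdm(aa=zeros, bb=zeros.copy(), ab=gamma_ab, kind="FCI")
    da = cmat @ cmat.T
    rdm1 = OneRdm(da, da.copy(), kind="FCI")
    return float(e0 + e_nuc), rdm1, rdm2


class _StringSpace:
    """Occupation strings and single-replacement lists for one spin channel."""

    def __init__(self, norb: int, nelec: int):
        self.norb = norb
        self.nelec = nelec
        self.strings = list(combinations(range(norb), nelec))
        self.index = {s: i for i, s in enumerate(self.strings)}
        self.n = len(self.strings)
        # rep[(p, q)] = (from_indices, to_indices, phases) for a+_p a_q
        self.rep: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for p in range(norb):
            for q in range(norb):
                src, dst, ph = [], [], []
                for i, s in enumerate(self.strings):
                    if q not in s:
                        continue
                    occ = list(s)
                    phase = (-1) ** occ.index(q)
                    occ.remove(q)
                    if p in occ:
                        continue
                    # insert p keeping sorted order
                    pos = sum(1 for o in occ if o < p)
                    phase *= (-1) ** pos
                    occ.insert(pos, p)
                    src.append(i)
                    dst.append(self.index[tuple(occ)])
                    ph.append(phase)
                self.rep[(p, q)] = (np.array(src, dtype=np.int64),
                                    np.array(dst, dtype=np.int64),
                                    np.array(ph, dtype=np.float64))

    def apply(self, p: int, q: int, c: np.ndarray, axis: int) -> np.ndarray:
        """E_pq acting on the CI tensor along the given spin axis."""
        src, dst, ph = self.rep[(p, q)]
        out = np.zeros_like(c)
        if axis == 0:
            out[dst, :] = ph[:, None] * c[src, :]
        else:
            out[:, dst] = ph[None, :] * c[:, src]
        return out


def _general_fci(h: np.ndarray, g: np.ndarray, na: int, nb: int, e_nuc: float):
    norb = h.shape[0]
    sa = _StringSpace(norb, na)
    sb = _StringSpace(norb, nb)
    ndet = sa.n * sb.n
    k1 = h - 0.5 * np.einsum("prrq->pq", g)
    gmat = g.reshape(norb * norb, norb * norb)

    def e_all(c):
        """T[pq] = (E^a_pq + E^b_pq) c, stacked as (norb^2, ndet)."""
        t = np.empty((norb * norb, sa.n, sb.n))
        for p in range(norb):
            for q in range(norb):
                t[p * norb + q] = (sa.apply(p, q, c, 0) + sb.apply(p, q, c, 1))
        return t

    def matvec(x):
        c = x.reshape(sa.n, sb.n)
        t = e_all(c)
        sig = np.tensordot(k1.reshape(-1), t, axes=(0, 0))
        gt = gmat @ t.reshape(norb * norb, ndet)
        gt = gt.reshape(norb, norb, sa.n, sb.n)
        for p in range(norb):
            for q in range(norb):
                sig += 0.5 * (sa.apply(p, q, gt[p, q], 0)
                              + sb.apply(p, q, gt[p, q], 1))
        return sig.reshape(-1)

    if ndet <= 600:
        # dense Hamiltonian via the operator action on unit vectors
        hmat = np.column_stack([matvec(col) for col in np.eye(ndet)])
        hmat = 0.5 * (hmat + hmat.T)
        w, v = np.linalg.eigh(hmat)
        e0, cvec = float(w[0]), v[:, 0]
    else:
        op = spla.LinearOperator((ndet, ndet), matvec=matvec, dtype=float)
        # start from the HF determinant
        v0 = np.zeros(ndet)
        v0[sa.index[tuple(range(na))] * sb.n + sb.index[tuple(range(nb))]] = 1.0
        w, v = spla.eigsh(op, k=1, which="SA", v0=v0, maxiter=2000, tol=1e-11)
        e0, cvec = float(w[0]), v[:, 0]
    c = cvec.reshape(sa.n, sb.n)

    # spin-blocked 2-RDM via replacement lists:
    #   G^{ss'}_{pqrs} = <E^s_qp psi | E^{s'}_rs psi>  (minus the same-spin
    #   contraction correction)
    ua = np.empty((norb * norb, ndet))
    ub = np.empty((norb * norb, ndet))
    for p in range(norb):
        for q in range(norb):
            ua[p * norb + q] = sa.apply(p, q, c, 0).reshape(-1)
            ub[p * norb + q] = sb.apply(p, q, c, 1).reshape(-1)
    da = np.array([[np.dot(ua[q * norb + p], c.reshape(-1))
                    for q in range(norb)] for p in range(norb)])
    db = np.array([[np.dot(ub[q * norb + p], c.reshape(-1))
                    for q in range(norb)] for p in range(norb)])
    # <E_pq E_rs> matrices
    ee_aa = (ua[_transp(norb)] @ ua.T).reshape(norb, norb, norb, norb)
    ee_bb = (ub[_transp(norb)] @ ub.T).reshape(norb, norb, norb, norb)
    ee_ab = (ua[_transp(norb)] @ ub.T).reshape(norb, norb, norb, norb)
    gaa = ee_aa - np.einsum("qr,ps->pqrs", np.eye(norb), da)
    gbb = ee_bb - np.einsum("qr,ps->pqrs", np.eye(norb), db)
    rdm1 = OneRdm(da, db, kind="FCI")
    rdm2 = TwoRdm(aa=gaa, bb=gbb, ab=ee_ab, kind="FCI")
    return e0 + e_nuc, rdm1, rdm2


def _transp(norb: int) -> np.ndarray:
    """Index permutation mapping row pq -> qp in the stacked operator array."""
    idx = np.arange(norb * norb).reshape(norb, norb)
    return idx.T.reshape(-1)


def fci_solve(scf: ScfSolution, max_electrons: int = MAX_ELECTRONS) -> FciResult:
    """Ground-state FCI energy and densities in the RHF MO basis.

    Restricted to ``max_electrons`` (default 4); raises
    ``UnsupportedSystemError`` beyond that.
    """
    n = scf.molecule.n_electrons
    if n > max_electrons:
        raise UnsupportedSystemError(
            f"FCI path supports up to {max_electrons} electrons, got {n}")
    c = scf.orbital_coefficients
    h = c.T @ scf.integrals.hcore @ c
    g = mo_eri(scf)
    e_nuc = scf.integrals.nuclear_repulsion
    if n == 2:
        energy, rdm1, rdm2 = _pair_ci(h, g, e_nuc)
    else:
        energy, rdm1, rdm2 = _general_fci(h, g, n // 2, n - n // 2, e_nuc)
    return FciResult(energy, rdm1, rdm2, energy - scf.e_hf)
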