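"""Spin-resolved one- and two-particle density matrices in the MO basis.

Conventions (real spatial MOs, chemist index pairing):

* ``OneRdm`` holds one matrix per spin; ``trace`` = N_sigma.
* ``TwoRdm`` holds blocks ``aa``, ``bb``, ``ab`` with
  ``G^{ss'}_{pqrs} = <a+_{p s} a+_{r s'} a_{s s'} a_{q s}>`` so that

  - Vee(same spin)   = 1/2 sum (G_aa + G_bb)_pqrs (pq|rs)
  - Vee(opposite)    =     sum  G_ab_pqrs (pq|rs)
  - OS pair count    = sum_p,r G_ab_pprr = N_a * N_b
  - SS pair count    = 1/2 sum_p,r (G_aa + G_bb)_pprr

The ``ab`` block stores alpha as the first pair; the beta-first block is its
pair transpose and is never stored.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["OneRdm", "TwoRdm", "hf_rdm1", "hf_rdm2", "VeeDecomposition"]


@dataclasses.dataclass
class OneRdm:
    """Per-spin one-particle density in the (canonical) MO basis."""

    alpha: np.ndarray
    beta: np.ndarray
    kind: str  # HF | MP2-unrelaxed | MP2-relaxed | FCI

    @property
    def spin_summed(self) -> np.ndarray:
        return self.alpha + self.beta

    def trace(self) -> tuple[float, float]:
        return float(np.trace(self.alpha)), float(np.trace(self.beta))

    def validate(self, n_alpha: int, n_beta: int, tol: float = 1e-8) -> None:
        ta, tb = self.trace()
        if abs(ta - n_alpha) > tol or abs(tb - n_beta) > tol:
            raise ValueError(f"1-RDM trace ({ta}, {tb}) != ({n_alpha}, {n_beta})")
        if (np.max(np.abs(self.alpha - self.alpha.T)) > tol
                or np.max(np.abs(self.beta - self.beta.T)) > tol):
            raise ValueError("1-RDM not symmetric")


@dataclasses.dataclass
class VeeDecomposition:
    """Electron-repulsion expectation split into spin channels (hartree)."""

    same_spin: float
    opposite_spin: float

    @property
    def total(self) -> float:
        return self.same_spin + self.opposite_spin


@dataclasses.dataclass
class TwoRdm:
    aa: np.ndarray
    bb: np.ndarray
    ab: np.ndarray
    kind: str

    @property
    def n_orb(self) -> int:
        return self.aa.shape[0]

    def pair_counts(self) -> VeeDecomposition:
        """(SS pairs, OS pairs) -- reuses the channel container."""
        ss = 0.5 * (np.einsum("pprr->", self.aa) + np.einsum("pprr->", self.bb))
        os_ = np.einsum("pprr->", self.ab)
        return VeeDecomposition(float(ss), float(os_))

    def vee(self, eri_mo: np.ndarray) -> VeeDecomposition:
        """<1/r12> from the two-particle density and MO integrals (pq|rs)."""
        ss = 0.5 * (np.einsum("pqrs,pqrs->", self.aa, eri_mo, optimize=True)
                    + np.einsum("pqrs,pqrs->", self.bb, eri_mo, optimize=True))
        os_ = np.einsum("pqrs,pqrs->", self.ab, eri_mo, optimize=True)
        return VeeDecomposition(float(ss), float(os_))

    def contract_to_rdm1(self, n_alpha: int, n_beta: int) -> OneRdm:
        """Partial trace; exact only for N-representable (e.g. FCI/HF) densities.

        sum_s G^{aa}_{pqss} = (N_a - 1) D^a_pq and sum_s G^{ab}_{pqss} = N_b D^a_pq.
        """
        if n_alpha > 1:
            da = np.einsum("pqss->pq", self.aa) / (n_alpha - 1)
        else:
            da = np.einsum("pqss->pq", self.ab) / max(n_beta, 1)
        if n_beta > 1:
            db = np.einsum("pqss->pq", self.bb) / (n_beta - 1)
        else:
            db = np.einsum("ssqp->qp", self.ab) / max(n_alpha, 1)
        return OneRdm(da, db, kind=self.kind)

    def validate_contraction(self, rdm1: OneRdm, n_alpha: int, n_beta: int,
                             tol: float = 1e-6) -> None:
        """Check the partial-trace sum rules against a reference 1-RDM."""
        defects = []
        if n_alpha > 1:
            defects.append(np.max(np.abs(
                np.einsum("pqss->pq", self.aa) - (n_alpha - 1) * rdm1.alpha)))
        if n_beta > 0:
            defects.append(np.max(np.abs(
                np.einsum("pqss->pq", self.ab) - n_beta * rdm1.alpha)))
        n = n_alpha + n_beta
        pairs = self.pair_counts()
        defects.append(abs(pairs.total - n * (n - 1) / 2))
        if max(defects) > tol:
            raise ValueError(f"2-RDM contraction defect {max(defects):.3e} > {tol:g}")


def hf_rdm1(n_occ: int, n_orb: int) -> OneRdm:
    d = np.zeros((n_orb, n_orb))
    d[np.diag_indices(n_occ)] = 1.0
    return OneRdm(d, d.copy(), kind="HF")


def hf_rdm2(n_occ: int, n_orb: int) -> TwoRdm:
    """Closed-shell single-determinant two-particle density."""
    d = hf_rdm1(n_occ, n_orb).alpha
    coul = np.einsum("pq,rs->pqrs", d, d)
    exch = np.einsum("ps,rq->pqrs", d, d)
    return TwoRdm(aa=coul - exch, bb=coul - exch, ab=coul, kind="HF")
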