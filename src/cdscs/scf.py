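"""Restricted Hartree-Fock with DIIS for closed-shell molecules."""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

from .basis import build_basis
from .integrals import IntegralSet, compute_integrals
from .molecule import Molecule

__all__ = ["ScfSolution", "run_rhf", "ScfError", "UnsupportedSystemError"]


class ScfError(RuntimeError):
    """SCF failed to converge."""


class UnsupportedSystemError(ValueError):
    """System outside the engine's closed-shell scope."""


@dataclasses.dataclass
class ScfSolution:
    """Converged RHF reference.

    ``orbital_coefficients`` columns are MOs over spherical AOs,
    ``orbital_energies`` ascending (hartree).  ``n_occupied`` is the number
    of doubly occupied spatial orbitals (= N_sigma per spin).
    """

    molecule: Molecule
    basis_label: str
    integrals: IntegralSet
    orbital_coefficients: np.ndarray
    orbital_energies: np.ndarray
    n_occupied: int
    e_hf: float
    converged: bool = True

    @property
    def n_basis(self) -> int:
        return self.integrals.n_basis

    @property
    def n_virtual(self) -> int:
        return self.n_basis - self.n_occupied

    def fock_build(self, density: np.ndarray) -> np.ndarray:
        """AO Fock matrix for a spin-summed AO density."""
        g = self.integrals.eri
        j = np.einsum("pqrs,rs->pq", g, density, optimize=True)
        k = np.einsum("prqs,rs->pq", g, density, optimize=True)
        return self.integrals.hcore + j - 0.5 * k

    def vee_hf(self) -> float:
        """HF electron-electron repulsion expectation (hartree)."""
        c_occ = self.orbital_coefficients[:, : self.n_occupied]
        d = 2.0 * c_occ @ c_occ.T
        g = self.integrals.eri
        j = np.einsum("pqrs,pq,rs->", g, d, d, optimize=True)
        k = np.einsum("prqs,pq,rs->", g, d, d, optimize=True)
        return 0.5 * j - 0.25 * k


def run_rhf(
    molecule: Molecule,
    basis: str,
    e_conv: float = 1e-9,
    d_conv: float = 1e-7,
    max_cycles: int = 128,
    integrals: IntegralSet | None = None,
) -> ScfSolution:
    """Converge a closed-shell RHF wavefunction.

    ``integrals`` overrides the computed AO integrals (used for perturbed
    Hamiltonians, e.g. finite-field checks).

    Raises
    ------
    UnsupportedSystemError
        for odd electron counts or multiplicity != 1.
    ScfError
        if the energy has not converged to ``e_conv`` after ``max_cycles``.
    """
    if molecule.multiplicity != 1 or molecule.n_electrons % 2:
        raise UnsupportedSystemError(
            f"{molecule.name or molecule.atoms}: restricted engine needs a "
            f"closed-shell singlet (N={molecule.n_electrons}, "
            f"2S+1={molecule.multiplicity})")
    if integrals is None:
        bas = build_basis(molecule, basis)
        ints = compute_integrals(molecule, bas)
    else:
        ints = integrals
    nocc = molecule.n_electrons // 2
    if nocc > ints.n_basis:
        raise UnsupportedSystemError("more electron pairs than basis functions")

    s, h, g = ints.overlap, ints.hcore, ints.eri
    # symmetric orthogonalization
    sval, svec = np.linalg.eigh(s)
    x = svec @ np.diag(sval ** -0.5) @ svec.T

    def fock(d):
        j = np.einsum("pqrs,rs->pq", g, d, optimize=True)
        k = np.einsum("prqs,rs->pq", g, d, optimize=True)
        return h + j - 0.5 * k

    e_mo, c_p = np.linalg.eigh(x @ h @ x)
    c = x @ c_p
    d = 2.0 * c[:, :nocc] @ c[:, :nocc].T
    e_old = 0.0
    diis_f, diis_r = [], []
    converged = False
    for _ in range(max_cycles):
        f = fock(d)
        # DIIS on the orthonormal-basis error F D S - S D F
        err = x @ (f @ d @ s - s @ d @ f) @ x
        diis_f.append(f)
        diis_r.append(err)
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_r.pop(0)
        if len(diis_f) > 1:
            n = len(diis_f)
            bmat = -np.ones((n + 1, n + 1))
            bmat[-1, -1] = 0.0
            for i in range(n):
                for jj in range(n):
                    bmat[i, jj] = np.sum(diis_r[i] * diis_r[jj])
            rhs = np.zeros(n + 1)
            rhs[-1] = -1.0
            try:
                w = np.linalg.solve(bmat, rhs)[:n]
                f = sum(wi * fi for wi, fi in zip(w, diis_f))
            except np.linalg.LinAlgError:
                pass
        e_mo, c_p = np.linalg.eigh(x @ f @ x)
        c = x @ c_p
        d_new = 2.0 * c[:, :nocc] @ c[:, :nocc].T
        e_el = 0.5 * np.sum(d_new * (h + fock(d_new)))
        de = abs(e_el - e_old)
        dd = np.max(np.abs(d_new - d))
        d, e_old = d_new, e_el
        if de < e_conv and dd < d_conv:
            converged = True
            break
    if not converged:
        raise ScfError(
            f"SCF on {molecule.name or molecule.atoms}/{basis} did not reach "
            f"dE<{e_conv:g} in {max_cycles} cycles")
    e_hf = e_old + ints.nuclear_repulsion
    return ScfSolution(molecule, ints.basis.name, ints, c, e_mo, nocc, e_hf)
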