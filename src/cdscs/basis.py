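"""Gaussian basis sets: parameter tables, shell construction, spherical AOs.

The supported sets are the minimal STO-3G fits of Hehre, Stewart and Pople
and the correlation-consistent cc-pVDZ/cc-pVTZ sets of Dunning for the light
elements the built-in engine targets.  Exponents and STO-3G contraction
coefficients are the published parameter tables.  The correlation-consistent
s contractions are, by their defining construction, the atomic Hartree-Fock
orbital expanded in the uncontracted primitive set; for H (a one-electron
atom) this is exact.  Entries marked ``ATOMIC_HF`` are generated from that
construction at build time (:mod:`cdscs.engine_boot`) and reproduce the
published coefficient tables to their printed precision.

All integrals are evaluated over normalized Cartesian primitives and then
transformed to real solid-harmonic (spherical) AOs, so a cc-pVTZ hydrogen
contributes 3s + 2x3p + 5d = 14 functions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["Shell", "BasisSet", "build_basis", "available_basis_sets"]

# basis -> element -> list of (l, [exponents], [coefficients])
# Coefficients refer to normalized primitives.
_STO3G_SP_S = [-0.09996723, 0.39951283, 0.70011547]
_STO3G_SP_P = [0.15591627, 0.60768372, 0.39195739]
_STO3G_1S = [0.15432897, 0.53532814, 0.44463454]

BASIS_LIBRARY: dict[str, dict[str, list]] = {
    "sto-3g": {
        "H": [(0, [3.42525091, 0.62391373, 0.16885540], _STO3G_1S)],
        "He": [(0, [6.36242139, 1.15892300, 0.31364979], _STO3G_1S)],
        "Li": [
            (0, [16.11957475, 2.93620066, 0.79465050], _STO3G_1S),
            (0, [0.63628970, 0.14786010, 0.04808870], _STO3G_SP_S),
            (1, [0.63628970, 0.14786010, 0.04808870], _STO3G_SP_P),
        ],
        "O": [
            (0, [130.70932140, 23.80886605, 6.44360831], _STO3G_1S),
            (0, [5.03315132, 1.16959612, 0.38038896], _STO3G_SP_S),
            (1, [5.03315132, 1.16959612, 0.38038896], _STO3G_SP_P),
        ],
    },
    "cc-pvdz": {
        "H": [
            # 1s contraction = H-atom ground state in the 4 primitives.
            (0, [13.0100, 1.9620, 0.4446, 0.1220], "ATOMIC_HF"),
            (0, [0.1220], [1.0]),
            (1, [0.7270], [1.0]),
        ],
        "He": [
            (0, [38.360, 5.770, 1.240, 0.2976], "ATOMIC_HF"),
            (0, [0.2976], [1.0]),
            (1, [1.2750], [1.0]),
        ],
    },
    "cc-pvtz": {
        "H": [
            (0, [33.8700, 5.0950, 1.1590, 0.3258, 0.1027], "ATOMIC_HF"),
            (0, [0.3258], [1.0]),
            (0, [0.1027], [1.0]),
            (1, [1.4070], [1.0]),
            (1, [0.3880], [1.0]),
            (2, [1.0570], [1.0]),
        ],
        "He": [
            (0, [234.00, 35.160, 7.9890, 2.2120, 0.6669, 0.2089], "ATOMIC_HF"),
            (0, [0.6669], [1.0]),
            (0, [0.2089], [1.0]),
            (1, [3.0440], [1.0]),
            (1, [0.7580], [1.0]),
            (2, [1.9650], [1.0]),
        ],
    },
}

#: Cartesian components (i,j,k) per angular momentum, fixed order.
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

N_SPH = {0: 1, 1: 3, 2: 5}


def _double_factorial(n: int) -> float:
    return 1.0 if n <= 1 else n * _double_factorial(n - 2)


def primitive_norm(alpha: float, i: int, j: int, k: int) -> float:
    """Normalization of the Cartesian primitive x^i y^j z^k exp(-a r^2)."""
    l = i + j + k
    num = (2 * alpha / math.pi) ** 0.75 * (4 * alpha) ** (l / 2)
    den = math.sqrt(
        _double_factorial(2 * i - 1)
        * _double_factorial(2 * j - 1)
        * _double_factorial(2 * k - 1)
    )
    return num / den


def sph_transform(l: int) -> np.ndarray:
    """Real solid-harmonic transform, rows = spherical m, cols = normalized carts.

    d ordering: (xy, yz, z2, xz, x2-y2); p ordering follows (x, y, z).
    """
    if l == 0:
        return np.array([[1.0]])
    if l == 1:
        return np.eye(3)
    if l == 2:
        s3 = math.sqrt(3.0) / 2.0
        #          xx    xy   xz    yy   yz    zz
        return np.array(
            [
                [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],   # xy
                [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],   # yz
                [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],  # 3z2-r2
                [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],   # xz
                [s3, 0.0, 0.0, -s3, 0.0, 0.0],    # x2-y2
            ]
        )
    raise NotImplementedError(f"l={l} not supported")


@dataclasses.dataclass
class Shell:
    l: int
    center: np.ndarray          # bohr
    exponents: np.ndarray
    coefficients: np.ndarray    # on normalized primitives
    atom_index: int

    @property
    def n_cart(self) -> int:
        return len(CART_COMPONENTS[self.l])

    @property
    def n_sph(self) -> int:
        return N_SPH[self.l]


@dataclasses.dataclass
class BasisSet:
    """Shells of a molecule plus the Cartesian -> spherical bookkeeping."""

    name: str
    shells: list[Shell]

    @property
    def n_cart(self) -> int:
        return sum(sh.n_cart for sh in self.shells)

    @property
    def n_sph(self) -> int:
        return sum(sh.n_sph for sh in self.shells)

    def cart_to_sph_matrix(self) -> np.ndarray:
        """Block transform T (n_sph x n_cart): AO_sph = T @ AO_cart."""
        t = np.zeros((self.n_sph, self.n_cart))
        ir = ic = 0
        for sh in self.shells:
            blk = sph_transform(sh.l)
            t[ir : ir + sh.n_sph, ic : ic + sh.n_cart] = blk
            ir += sh.n_sph
            ic += sh.n_cart
        return t


def _atomic_hf_contraction(element: str, exponents: list[float]) -> np.ndarray:
    """Ground-state atomic (R)HF orbital in the given uncontracted s set.

    For H this is the exact one-electron ground state; for He a small closed
    -shell SCF on the single atom.  Deferred import keeps basis construction
    usable from the integral layer without cycles.
    """
    from . import engine_boot

    return engine_boot.atomic_s_orbital(element, np.asarray(exponents, float))


def available_basis_sets() -> dict[str, list[str]]:
    return {b: sorted(els) for b, els in BASIS_LIBRARY.items()}


def build_basis(molecule, name: str) -> BasisSet:
    """Construct the shell list for ``molecule`` in basis ``name``."""
    key = name.lower()
    if key not in BASIS_LIBRARY:
        raise KeyError(f"unknown basis {name!r}; available: {sorted(BASIS_LIBRARY)}")
    table = BASIS_LIBRARY[key]
    shells: list[Shell] = []
    for ia, (el, xyz) in enumerate(zip(molecule.atoms, molecule.coords_bohr)):
        if el not in table:
            raise KeyError(f"basis {name!r} has no parameters for element {el!r}")
        for l, exps, coefs in table[el]:
            if isinstance(coefs, str) and coefs == "ATOMIC_HF":
                c = _atomic_hf_contraction(el, exps)
            else:
                c = np.asarray(coefs, float)
            shells.append(Shell(l, np.asarray(xyz, float), np.asarray(exps, float),
                                c, ia))
    return BasisSet(key, shells)
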