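"""Single-atom s-only HF used to generate general-contraction coefficients.

Correlation-consistent s contractions are defined as the atomic HF orbital
expanded in the uncontracted primitive set.  For one-center s functions every
integral has a closed form, so this tiny solver has no dependency on the
general integral machinery (which in turn consumes the contractions).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import eigh

from .constants import NUCLEAR_CHARGE

__all__ = ["atomic_s_orbital"]


def _s_matrices(z: float, a: np.ndarray):
    """Overlap, kinetic, nuclear attraction over normalized concentric s primitives."""
    norm = (2.0 * a / math.pi) ** 0.75
    ai, aj = np.meshgrid(a, a, indexing="ij")
    p = ai + aj
    nn = np.outer(norm, norm)
    s = nn * (math.pi / p) ** 1.5
    t = 3.0 * ai * aj / p * s
    v = -z * nn * 2.0 * math.pi / p
    return s, t, v


def _s_eri(a: np.ndarray) -> np.ndarray:
    """(ab|cd) over normalized concentric s primitives, closed form."""
    n = len(a)
    norm = (2.0 * a / math.pi) ** 0.75
    g = np.empty((n, n, n, n))
    for i in range(n):
        for j in range(n):
            p = a[i] + a[j]
            for k in range(n):
                for l in range(n):
                    q = a[k] + a[l]
                    g[i, j, k, l] = (
                        2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
                        * norm[i] * norm[j] * norm[k] * norm[l]
                    )
    return g


def atomic_s_orbital(element: str, exponents: np.ndarray) -> np.ndarray:
    """HF 1s orbital coefficients (on normalized primitives) for H or He."""
    z = float(NUCLEAR_CHARGE[element])
    s, t, v = _s_matrices(z, exponents)
    h = t + v
    if element == "H":
        _, c = eigh(h, s)
        orb = c[:, 0]
    elif element == "He":
        g = _s_eri(exponents)
        _, c = eigh(h, s)
        orb = c[:, 0]
        for _ in range(200):
            d = 2.0 * np.outer(orb, orb)
            jmat = np.einsum("ijkl,kl->ij", g, d)
            kmat = np.einsum("ikjl,kl->ij", g, d)
            f = h + jmat - 0.5 * kmat
            _, c = eigh(f, s)
            new = c[:, 0]
            if np.linalg.norm(np.abs(new) - np.abs(orb)) < 1e-12:
                orb = new
                break
            orb = new
    else:
        raise NotImplementedError(f"atomic contraction generator supports H/He, got {element}")
    if orb[np.argmax(np.abs(orb))] < 0:
        orb = -orb
    return orb
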