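"""Molecular quadrature grids and AO evaluation for intracule integration.

Atom-centered grids: Murray-Handy-Laming radial points r_i = R (i/(n+1-i))^2
with Gauss-Legendre x uniform-phi angular shells, combined with Becke's
smooth Voronoi partition.  Accuracy is certified downstream by sum rules
(electron count, pair count), not assumed from the grid parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .basis import CART_COMPONENTS, BasisSet, primitive_norm, sph_transform

__all__ = ["GridSpec", "molecular_grid", "ao_values"]

#: Becke-style per-element radius scale (bohr) for the radial map.
_ATOM_R = {"H": 1.0, "He": 1.0, "Li": 2.0, "Be": 1.7, "B": 1.5, "C": 1.3,
           "N": 1.2, "O": 1.1, "F": 1.0, "Ne": 0.9}


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Quadrature controls.  Defaults suit few-electron diatomics."""

    n_radial: int = 35
    n_theta: int = 10
    n_phi: int = 20
    becke_k: int = 3


def _radial(n: int, r_scale: float):
    i = np.arange(1, n + 1, dtype=float)
    x = i / (n + 1.0 - i)
    r = r_scale * x * x
    # dr/di = R * 2 x (n+1) / (n+1-i)^2
    dr = r_scale * 2.0 * x * (n + 1.0) / (n + 1.0 - i) ** 2
    w = dr * r * r
    return r, w


def _angular(n_theta: int, n_phi: int):
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    wphi = 2.0 * np.pi / n_phi
    ct, p = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct * ct)
    pts = np.stack([st * np.cos(p), st * np.sin(p), ct], axis=-1).reshape(-1, 3)
    w = (wx[:, None] * wphi * np.ones(n_phi)[None, :]).reshape(-1)
    return pts, w


def _becke_weights(points: np.ndarray, centers: np.ndarray, k: int) -> np.ndarray:
    """Smooth Voronoi cell weights; ``points`` (N,3), one column per atom."""
    natom = len(centers)
    if natom == 1:
        return np.ones((len(points), 1))
    dist = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    rij = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    cell = np.ones((len(points), natom))
    for i in range(natom):
        for j in range(natom):
            if i == j:
                continue
            mu = (dist[:, i] - dist[:, j]) / rij[i, j]
            f = mu
            for _ in range(k):
                f = 1.5 * f - 0.5 * f ** 3
            cell[:, i] *= 0.5 * (1.0 - f)
    return cell / cell.sum(axis=1, keepdims=True)


def molecular_grid(molecule, spec: GridSpec = GridSpec()):
    """Becke-partitioned quadrature: returns points (N,3, bohr) and weights."""
    centers = molecule.coords_bohr
    ang_pts, ang_w = _angular(spec.n_theta, spec.n_phi)
    pts, wts, owner = [], [], []
    for ia, (el, c) in enumerate(zip(molecule.atoms, centers)):
        r, wr = _radial(spec.n_radial, _ATOM_R.get(el, 1.0))
        p = (r[:, None, None] * ang_pts[None, :, :] + c).reshape(-1, 3)
        w = (wr[:, None] * ang_w[None, :]).reshape(-1)
        pts.append(p)
        wts.append(w)
        owner.append(np.full(len(w), ia))
    points = np.concatenate(pts)
    weights = np.concatenate(wts)
    owner = np.concatenate(owner)
    becke = _becke_weights(points, centers, spec.becke_k)
    weights = weights * becke[np.arange(len(points)), owner]
    return points, weights


def ao_values(basis: BasisSet, points: np.ndarray,
              ao_normalization: np.ndarray | None = None) -> np.ndarray:
    """Spherical AO values at grid points (N, n_sph), matching IntegralSet."""
    n = len(points)
    cart_cols = []
    for sh in basis.shells:
        d = points - sh.center
        r2 = np.einsum("ni,ni->n", d, d)
        rad = np.zeros(n)
        for a, cc in zip(sh.exponents, sh.coefficients):
            rad = rad + cc * primitive_norm(a, sh.l, 0, 0) * np.exp(-a * r2)
        # per-component norm ratio relative to the axial component
        ax_norm = primitive_norm(sh.exponents[0], sh.l, 0, 0)
        for (i, j, k) in CART_COMPONENTS[sh.l]:
            ratio = primitive_norm(sh.exponents[0], i, j, k) / ax_norm
            poly = d[:, 0] ** i * d[:, 1] ** j * d[:, 2] ** k
            cart_cols.append(ratio * rad * poly)
    cart = np.stack(cart_cols, axis=1)
    sph = cart @ _block_transform(basis).T
    if ao_normalization is not None:
        sph = sph * ao_normalization[None, :]
    return sph


def _block_transform(basis: BasisSet) -> np.ndarray:
    t = np.zeros((basis.n_sph, basis.n_cart))
    ir = ic = 0
    for sh in basis.shells:
        blk = sph_transform(sh.l)
        t[ir : ir + sh.n_sph, ic : ic + sh.n_cart] = blk
        ir += sh.n_sph
        ic += sh.n_cart
    return t
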