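"""AO integrals over contracted Cartesian Gaussians (McMurchie-Davidson).

One numba-compiled kernel per integral class; drivers assemble full matrices
in the Cartesian primitive basis, transform to real solid harmonics and
renormalize the contracted AOs.  Supported angular momenta: s, p, d.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import CART_COMPONENTS, BasisSet

__all__ = ["IntegralSet", "compute_integrals"]

_LMAX = 2
_MAXCOMP = 6


@njit(cache=True)
def _boys(mmax, x, out):
    """Boys function F_m(x) for m = 0..mmax via series + downward recursion."""
    if x < 1e-14:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if x > 35.0:
        # asymptotic F_m = (2m-1)!! / 2^{m+1} * sqrt(pi / x^{2m+1})
        out[0] = 0.5 * np.sqrt(np.pi / x)
        for m in range(1, mmax + 1):
            out[m] = out[m - 1] * (2 * m - 1) / (2.0 * x)
        return
    # series at the highest order, then downward
    acc = 0.0
    term = 1.0 / (2 * mmax + 1)
    k = 0
    while True:
        acc += term
        k += 1
        term *= 2.0 * x / (2 * mmax + 2 * k + 1)
        if term < 1e-17 * acc or k > 300:
            break
    ex = np.exp(-x)
    out[mmax] = acc * ex
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * x * out[m + 1] + ex) / (2 * m + 1)


@njit(cache=True)
def _hermite_e(i_max, j_max, a, b, ab, etab):
    """Hermite expansion coefficients E^{ij}_t along one axis.

    ``ab`` is A-B on this axis; fills etab[i, j, t] for t <= i+j.
    """
    p = a + b
    mu = a * b / p
    etab[:, :, :] = 0.0
    etab[0, 0, 0] = np.exp(-mu * ab * ab)
    pa = -b * ab / p   # P - A
    pb = a * ab / p    # P - B
    for i in range(i_max + 1):
        for j in range(j_max + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + 1):
                    val = pa * etab[i - 1, 0, t]
                    if t > 0:
                        val += etab[i - 1, 0, t - 1] / (2 * p)
                    if t + 1 <= i - 1:
                        val += (t + 1) * etab[i - 1, 0, t + 1]
                    etab[i, 0, t] = val
            else:
                for t in range(i + j + 1):
                    val = pb * etab[i, j - 1, t]
                    if t > 0:
                        val += etab[i, j - 1, t - 1] / (2 * p)
                    if t + 1 <= i + j - 1:
                        val += (t + 1) * etab[i, j - 1, t + 1]
                    etab[i, j, t] = val


@njit(cache=True)
def _hermite_r(tmax, umax, vmax, p, x, y, z, rtab):
    """Hermite Coulomb integrals R^0_{tuv}(p, PC); rtab[t,u,v]."""
    order = tmax + umax + vmax
    r2 = x * x + y * y + z * z
    fb = np.zeros(order + 1)
    _boys(order, p * r2, fb)
    # rn[n, t, u, v]
    rn = np.zeros((order + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(order + 1):
        rn[n, 0, 0, 0] = (-2.0 * p) ** n * fb[n]
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                if t + u + v == 0:
                    continue
                for n in range(order - (t + u + v), -1, -1):
                    if t > 0:
                        val = x * rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = y * rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * rn[n + 1, t, u - 2, v]
                    else:
                        val = z * rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * rn[n + 1, t, u, v - 2]
                    rn[n, t, u, v] = val
    rtab[: tmax + 1, : umax + 1, : vmax + 1] = rn[0]


@njit(cache=True)
def _one_electron(shl_l, shl_cent, shl_nprim, shl_exp, shl_coef,
                  comp_off, comp_xyz, ncart, atom_z, atom_xyz):
    """Overlap, kinetic and nuclear-attraction matrices (Cartesian basis)."""
    nsh = shl_l.shape[0]
    s_mat = np.zeros((ncart, ncart))
    t_mat = np.zeros((ncart, ncart))
    v_mat = np.zeros((ncart, ncart))
    # cartesian offsets per shell
    offs = np.zeros(nsh + 1, np.int64)
    for i in range(nsh):
        nc = comp_off[shl_l[i] + 1] - comp_off[shl_l[i]]
        offs[i + 1] = offs[i] + nc
    e_x = np.zeros((_LMAX + 3, _LMAX + 3, 2 * _LMAX + 6))
    e_y = np.zeros_like(e_x)
    e_z = np.zeros_like(e_x)
    rtab = np.zeros((2 * _LMAX + 1, 2 * _LMAX + 1, 2 * _LMAX + 1))
    natom = atom_z.shape[0]
    for ish in range(nsh):
        la = shl_l[ish]
        ca = shl_cent[ish]
        for jsh in range(ish + 1):
            lb = shl_l[jsh]
            cb = shl_cent[jsh]
            abx = ca[0] - cb[0]
            aby = ca[1] - cb[1]
            abz = ca[2] - cb[2]
            nca = comp_off[la + 1] - comp_off[la]
            ncb = comp_off[lb + 1] - comp_off[lb]
            sblk = np.zeros((nca, ncb))
            tblk = np.zeros((nca, ncb))
            vblk = np.zeros((nca, ncb))
            for ip in range(shl_nprim[ish]):
                a = shl_exp[ish, ip]
                da = shl_coef[ish, ip]
                for jp in range(shl_nprim[jsh]):
                    b = shl_exp[jsh, jp]
                    db = shl_coef[jsh, jp]
                    p = a + b
                    px = (a * ca[0] + b * cb[0]) / p
                    py = (a * ca[1] + b * cb[1]) / p
                    pz = (a * ca[2] + b * cb[2]) / p
                    # E tables up to la (+2 for kinetic on ket)
                    _hermite_e(la, lb + 2, a, b, abx, e_x)
                    _hermite_e(la, lb + 2, a, b, aby, e_y)
                    _hermite_e(la, lb + 2, a, b, abz, e_z)
                    sfac = (np.pi / p) ** 1.5
                    for ia in range(nca):
                        ax = comp_xyz[comp_off[la] + ia, 0]
                        ay = comp_xyz[comp_off[la] + ia, 1]
                        az = comp_xyz[comp_off[la] + ia, 2]
                        na = primitive_norm_nb(a, ax, ay, az)
                        for ib in range(ncb):
                            bx = comp_xyz[comp_off[lb] + ib, 0]
                            by = comp_xyz[comp_off[lb] + ib, 1]
                            bz = comp_xyz[comp_off[lb] + ib, 2]
                            nb = primitive_norm_nb(b, bx, by, bz)
                            cc = da * db * na * nb
                            # overlap
                            sv = e_x[ax, bx, 0] * e_y[ay, by, 0] * e_z[az, bz, 0] * sfac
                            sblk[ia, ib] += cc * sv
                            # kinetic: -1/2 sum over d2/dx2 etc on ket
                            tv = 0.0
                            # x part
                            term = -2.0 * b * b * e_x[ax, bx + 2, 0]
                            term += b * (2 * bx + 1) * e_x[ax, bx, 0]
                            if bx >= 2:
                                term -= 0.5 * bx * (bx - 1) * e_x[ax, bx - 2, 0]
                            tv += term * e_y[ay, by, 0] * e_z[az, bz, 0]
                            term = -2.0 * b * b * e_y[ay, by + 2, 0]
                            term += b * (2 * by + 1) * e_y[ay, by, 0]
                            if by >= 2:
                                term -= 0.5 * by * (by - 1) * e_y[ay, by - 2, 0]
                            tv += term * e_x[ax, bx, 0] * e_z[az, bz, 0]
                            term = -2.0 * b * b * e_z[az, bz + 2, 0]
                            term += b * (2 * bz + 1) * e_z[az, bz, 0]
                            if bz >= 2:
                                term -= 0.5 * bz * (bz - 1) * e_z[az, bz - 2, 0]
                            tv += term * e_x[ax, bx, 0] * e_y[ay, by, 0]
                            tblk[ia, ib] += cc * tv * sfac
                            # nuclear attraction
                            vv = 0.0
                            for iat in range(natom):
                                pcx = px - atom_xyz[iat, 0]
                                pcy = py - atom_xyz[iat, 1]
                                pcz = pz - atom_xyz[iat, 2]
                                _hermite_r(ax + bx, ay + by, az + bz, p,
                                           pcx, pcy, pcz, rtab)
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    for u in range(ay + by + 1):
                                        for v in range(az + bz + 1):
                                            acc += (e_x[ax, bx, t] * e_y[ay, by, u]
                                                    * e_z[az, bz, v] * rtab[t, u, v])
                                vv -= atom_z[iat] * acc
                            vblk[ia, ib] += cc * vv * 2.0 * np.pi / p
            for ia in range(nca):
                for ib in range(ncb):
                    s_mat[offs[ish] + ia, offs[jsh] + ib] = sblk[ia, ib]
                    s_mat[offs[jsh] + ib, offs[ish] + ia] = sblk[ia, ib]
                    t_mat[offs[ish] + ia, offs[jsh] + ib] = tblk[ia, ib]
                    t_mat[offs[jsh] + ib, offs[ish] + ia] = tblk[ia, ib]
                    v_mat[offs[ish] + ia, offs[jsh] + ib] = vblk[ia, ib]
                    v_mat[offs[jsh] + ib, offs[ish] + ia] = vblk[ia, ib]
    return s_mat, t_mat, v_mat


@njit(cache=True)
def primitive_norm_nb(alpha, i, j, k):
    l = i + j + k
    df = 1.0
    for n in (2 * i - 1, 2 * j - 1, 2 * k - 1):
        m = n
        while m > 1:
            df *= m
            m -= 2
    return (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / np.sqrt(df)


@njit(cache=True)
def _eri(shl_l, shl_cent, shl_nprim, shl_exp, shl_coef, comp_off, comp_xyz, ncart):
    """Full Cartesian-basis two-electron integral tensor (pq|rs)."""
    nsh = shl_l.shape[0]
    offs = np.zeros(nsh + 1, np.int64)
    for i in range(nsh):
        nc = comp_off[shl_l[i] + 1] - comp_off[shl_l[i]]
        offs[i + 1] = offs[i] + nc
    g = np.zeros((ncart, ncart, ncart, ncart))
    e1x = np.zeros((_LMAX + 1, _LMAX + 1, 2 * _LMAX + 1))
    e1y = np.zeros_like(e1x)
    e1z = np.zeros_like(e1x)
    e2x = np.zeros_like(e1x)
    e2y = np.zeros_like(e1x)
    e2z = np.zeros_like(e1x)
    dim = 4 * _LMAX + 1
    rtab = np.zeros((dim, dim, dim))
    for ish in range(nsh):
        la = shl_l[ish]
        ca = shl_cent[ish]
        nca = comp_off[la + 1] - comp_off[la]
        for jsh in range(ish + 1):
            lb = shl_l[jsh]
            cb = shl_cent[jsh]
            ncb = comp_off[lb + 1] - comp_off[lb]
            for ksh in range(ish + 1):
                lc = shl_l[ksh]
                cc_ = shl_cent[ksh]
                ncc = comp_off[lc + 1] - comp_off[lc]
                lsh_max = jsh if ksh == ish else ksh
                for lsh in range(lsh_max + 1):
                    ld = shl_l[lsh]
                    cd = shl_cent[lsh]
                    ncd = comp_off[ld + 1] - comp_off[ld]
                    blk = np.zeros((nca, ncb, ncc, ncd))
                    for ip in range(shl_nprim[ish]):
                        a = shl_exp[ish, ip]
                        for jp in range(shl_nprim[jsh]):
                            b = shl_exp[jsh, jp]
                            p = a + b
                            px = (a * ca[0] + b * cb[0]) / p
                            py = (a * ca[1] + b * cb[1]) / p
                            pz = (a * ca[2] + b * cb[2]) / p
                            _hermite_e(la, lb, a, b, ca[0] - cb[0], e1x)
                            _hermite_e(la, lb, a, b, ca[1] - cb[1], e1y)
                            _hermite_e(la, lb, a, b, ca[2] - cb[2], e1z)
                            dab = shl_coef[ish, ip] * shl_coef[jsh, jp]
                            for kp in range(shl_nprim[ksh]):
                                c = shl_exp[ksh, kp]
                                for lp in range(shl_nprim[lsh]):
                                    d = shl_exp[lsh, lp]
                                    q = c + d
                                    qx = (c * cc_[0] + d * cd[0]) / q
                                    qy = (c * cc_[1] + d * cd[1]) / q
                                    qz = (c * cc_[2] + d * cd[2]) / q
                                    _hermite_e(lc, ld, c, d, cc_[0] - cd[0], e2x)
                                    _hermite_e(lc, ld, c, d, cc_[1] - cd[1], e2y)
                                    _hermite_e(lc, ld, c, d, cc_[2] - cd[2], e2z)
                                    dcd = shl_coef[ksh, kp] * shl_coef[lsh, lp]
                                    alpha = p * q / (p + q)
                                    pref = (2.0 * np.pi ** 2.5
                                            / (p * q * np.sqrt(p + q)))
                                    _hermite_r(la + lb + lc + ld,
                                               la + lb + lc + ld,
                                               la + lb + lc + ld,
                                               alpha, px - qx, py - qy, pz - qz,
                                               rtab)
                                    for ia in range(nca):
                                        ax = comp_xyz[comp_off[la] + ia, 0]
                                        ay = comp_xyz[comp_off[la] + ia, 1]
                                        az = comp_xyz[comp_off[la] + ia, 2]
                                        na = primitive_norm_nb(a, ax, ay, az)
                                        for ib in range(ncb):
                                            bx = comp_xyz[comp_off[lb] + ib, 0]
                                            by = comp_xyz[comp_off[lb] + ib, 1]
                                            bz = comp_xyz[comp_off[lb] + ib, 2]
                                            nb = primitive_norm_nb(b, bx, by, bz)
                                            for ic in range(ncc):
                                                cx = comp_xyz[comp_off[lc] + ic, 0]
                                                cy = comp_xyz[comp_off[lc] + ic, 1]
                                                cz = comp_xyz[comp_off[lc] + ic, 2]
                                                nc_ = primitive_norm_nb(c, cx, cy, cz)
                                                for id_ in range(ncd):
                                                    dx = comp_xyz[comp_off[ld] + id_, 0]
                                                    dy = comp_xyz[comp_off[ld] + id_, 1]
                                                    dz = comp_xyz[comp_off[ld] + id_, 2]
                                                    nd = primitive_norm_nb(d, dx, dy, dz)
                                                    acc = 0.0
                                                    for t in range(ax + bx + 1):
                                                        for u in range(ay + by + 1):
                                                            for v in range(az + bz + 1):
                                                                e12 = (e1x[ax, bx, t]
                                                                       * e1y[ay, by, u]
                                                                       * e1z[az, bz, v])
                                                                if e12 == 0.0:
                                                                    continue
                                                                acc2 = 0.0
                                                                for tt in range(cx + dx + 1):
                                                                    for uu in range(cy + dy + 1):
                                                                        for vv in range(cz + dz + 1):
                                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                            acc2 += (sgn
                                                                                     * e2x[cx, dx, tt]
                                                                                     * e2y[cy, dy, uu]
                                                                                     * e2z[cz, dz, vv]
                                                                                     * rtab[t + tt, u + uu, v + vv])
                                                                acc += e12 * acc2
                                                    blk[ia, ib, ic, id_] += (
                                                        dab * dcd * pref * acc
                                                        * na * nb * nc_ * nd)
                    # scatter with 8-fold symmetry
                    for ia in range(nca):
                        for ib in range(ncb):
                            for ic in range(ncc):
                                for id_ in range(ncd):
                                    val = blk[ia, ib, ic, id_]
                                    pp = offs[ish] + ia
                                    qq = offs[jsh] + ib
                                    rr = offs[ksh] + ic
                                    ss = offs[lsh] + id_
                                    g[pp, qq, rr, ss] = val
                                    g[qq, pp, rr, ss] = val
                                    g[pp, qq, ss, rr] = val
                                    g[qq, pp, ss, rr] = val
                                    g[rr, ss, pp, qq] = val
                                    g[ss, rr, pp, qq] = val
                                    g[rr, ss, qq, pp] = val
                                    g[ss, rr, qq, pp] = val
    return g


class IntegralSet:
    """AO integrals in the normalized spherical-harmonic basis."""

    def __init__(self, s, t, v, eri, basis: BasisSet, e_nuc: float,
                 ao_normalization=None):
        self.overlap = s
        self.kinetic = t
        self.nuclear = v
        self.eri = eri
        self.basis = basis
        self.nuclear_repulsion = e_nuc
        # per-AO rescale applied on top of the raw spherical transform;
        # grid evaluation of AOs must apply the same factors
        self.ao_normalization = ao_normalization

    @property
    def hcore(self) -> np.ndarray:
        return self.kinetic + self.nuclear

    @property
    def n_basis(self) -> int:
        return self.overlap.shape[0]


def _pack_shells(basis: BasisSet):
    nsh = len(basis.shells)
    maxprim = max(len(sh.exponents) for sh in basis.shells)
    shl_l = np.zeros(nsh, np.int64)
    shl_cent = np.zeros((nsh, 3))
    shl_nprim = np.zeros(nsh, np.int64)
    shl_exp = np.zeros((nsh, maxprim))
    shl_coef = np.zeros((nsh, maxprim))
    for i, sh in enumerate(basis.shells):
        shl_l[i] = sh.l
        shl_cent[i] = sh.center
        shl_nprim[i] = len(sh.exponents)
        shl_exp[i, : len(sh.exponents)] = sh.exponents
        shl_coef[i, : len(sh.coefficients)] = sh.coefficients
    comp_off = np.zeros(_LMAX + 2, np.int64)
    comps = []
    for l in range(_LMAX + 1):
        comp_off[l + 1] = comp_off[l] + len(CART_COMPONENTS[l])
        comps.extend(CART_COMPONENTS[l])
    comp_xyz = np.array(comps, np.int64)
    return shl_l, shl_cent, shl_nprim, shl_exp, shl_coef, comp_off, comp_xyz


def compute_integrals(molecule, basis: BasisSet) -> IntegralSet:
    """All AO integrals for ``molecule`` in ``basis`` (spherical, normalized)."""
    packed = _pack_shells(basis)
    ncart = basis.n_cart
    s_c, t_c, v_c = _one_electron(*packed, ncart, molecule.nuclear_charges,
                                  molecule.coords_bohr)
    g_c = _eri(*packed[:5], packed[5], packed[6], ncart)
    tmat = basis.cart_to_sph_matrix()
    s = tmat @ s_c @ tmat.T
    t = tmat @ t_c @ tmat.T
    v = tmat @ v_c @ tmat.T
    g = np.einsum("pi,qj,rk,sl,ijkl->pqrs", tmat, tmat, tmat, tmat, g_c,
                  optimize=True)
    # renormalize contracted spherical AOs to unit self-overlap
    scale = 1.0 / np.sqrt(np.diag(s))
    s = s * scale[:, None] * scale[None, :]
    t = t * scale[:, None] * scale[None, :]
    v = v * scale[:, None] * scale[None, :]
    g = np.einsum("pqrs,p,q,r,s->pqrs", g, scale, scale, scale, scale,
                  optimize=True)
    return IntegralSet(s, t, v, g, basis, molecule.nuclear_repulsion(),
                       ao_normalization=scale)
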