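"""MP2 components, unrelaxed occupancies and relaxed densities."""

import copy

import numpy as np
import pytest

from cdscs import mp2 as m
from cdscs.rdm import hf_rdm1, hf_rdm2
from cdscs.scf import run_rhf


def brute_force_mp2(scf):
    """Explicit-loop spin-component MP2 (the independent oracle)."""
    g = m.mo_eri(scf)
    nocc, nbf = scf.n_occupied, scf.n_basis
    eps = scf.orbital_energies
    e_os = e_ss = 0.0
    for i in range(nocc):
        for j in range(nocc):
            for a in range(nocc, nbf):
                for b in range(nocc, nbf):
                    d = eps[i] + eps[j] - eps[a] - eps[b]
                    e_os += g[i, a, j, b] ** 2 / d
                    e_ss += g[i, a, j, b] * (g[i, a, j, b] - g[i, b, j, a]) / d
    return e_os, e_ss


def test_components_match_brute_force_loops(h2o_sto3g):
    mp2 = h2o_sto3g.mp2
    e_os, e_ss = brute_force_mp2(h2o_sto3g.scf)
    assert mp2.e_os == pytest.approx(e_os, abs=1e-12)
    assert mp2.e_ss == pytest.approx(e_ss, abs=1e-12)
    assert mp2.e_os <= 0 and mp2.e_ss <= 0


def test_two_electron_singlet_has_no_same_spin_correlation(h2_tz, he_dz):
    assert h2_tz.mp2.e_ss == pytest.approx(0.0, abs=1e-14)
    assert he_dz.mp2.e_ss == pytest.approx(0.0, abs=1e-14)
    assert h2_tz.mp2.e_os < 0


def test_doubling_denominators_halves_each_component(h2o_sto3g):
    """E_OS and E_SS are linear in 1/Delta at fixed integrals."""
    scf = copy.copy(h2o_sto3g.scf)
    scf.orbital_energies = 2.0 * h2o_sto3g.scf.orbital_energies
    doubled = m.mp2_components(scf)
    assert doubled.e_os == pytest.approx(0.5 * h2o_sto3g.mp2.e_os, rel=1e-12)
    assert doubled.e_ss == pytest.approx(0.5 * h2o_sto3g.mp2.e_ss, rel=1e-12)


def test_frozen_core_shrinks_correlation(h2o_sto3g):
    fc = m.mp2_components(h2o_sto3g.scf, frozen_core=True)
    ae = h2o_sto3g.mp2
    assert fc.n_frozen == 1
    assert 0 > fc.e_corr > ae.e_corr
    assert fc.t2.shape[0] == ae.t2.shape[0] - 1


def brute_force_unrelaxed_density(scf, mp2):
    """Quadratic amplitude corrections by explicit loops (per spin)."""
    nocc, nbf = scf.n_occupied, scf.n_basis
    nvir = nbf - nocc
    t = mp2.t2
    d = np.zeros((nbf, nbf))
    d[np.diag_indices(nocc)] = 1.0
    for i in range(nocc):
        for j in range(nocc):
            for k in range(nocc):
                for a in range(nvir):
                    for b in range(nvir):
                        d[i, j] -= t[i, k, a, b] * (2 * t[j, k, a, b]
                                                    - t[j, k, b, a])
    for a in range(nvir):
        for b in range(nvir):
            for i in range(nocc):
                for j in range(nocc):
                    for c in range(nvir):
                        d[nocc + a, nocc + b] += t[i, j, a, c] * (
                            2 * t[i, j, b, c] - t[i, j, c, b])
    return d


def test_unrelaxed_density_matches_explicit_loops(h2_dz):
    ref = brute_force_unrelaxed_density(h2_dz.scf, h2_dz.mp2)
    d = m.unrelaxed_rdm1(h2_dz.scf, h2_dz.mp2)
    assert np.max(np.abs(d.alpha - ref)) < 1e-12
    spectrum = m.unrelaxed_occupancies(h2_dz.scf, h2_dz.mp2)
    ref_occ = np.sort(np.linalg.eigvalsh(ref))[::-1]
    assert np.allclose(spectrum.alpha, ref_occ, atol=1e-8)


@pytest.mark.parametrize("engine", ["h2_dz", "h2o_sto3g", "h2_tz"])
def test_occupancies_in_unit_interval_and_trace_conserved(engine, request):
    eng = request.getfixturevalue(engine)
    spectrum = m.unrelaxed_occupancies(eng.scf, eng.mp2)
    n_sigma = eng.scf.n_occupied
    for chan in (spectrum.alpha, spectrum.beta):
        assert chan.min() >= 0.0 and chan.max() <= 1.0
        assert chan.sum() == pytest.approx(n_sigma, abs=1e-8)


def test_zero_amplitudes_collapse_to_hf(h2_dz):
    """Forcing t2 = 0 must reduce every MP2-derived quantity to HF."""
    mp2 = copy.copy(h2_dz.mp2)
    mp2.t2 = np.zeros_like(h2_dz.mp2.t2)
    scf = h2_dz.scf
    d1 = m.unrelaxed_rdm1(scf, mp2)
    assert np.allclose(d1.alpha, hf_rdm1(scf.n_occupied, scf.n_basis).alpha)
    r1, r2 = m.relaxed_densities(scf, mp2, h2_dz.g)
    hf2 = hf_rdm2(scf.n_occupied, scf.n_basis)
    assert np.allclose(r1.alpha, hf_rdm1(scf.n_occupied, scf.n_basis).alpha,
                       atol=1e-12)
    for blk in ("aa", "bb", "ab"):
        assert np.allclose(getattr(r2, blk), getattr(hf2, blk), atol=1e-12)


@pytest.mark.parametrize("engine", ["h2_dz", "h2o_sto3g"])
def test_relaxed_densities_reproduce_total_energy(engine, request):
    """tr(h D) + Vee[Gamma] + E_nuc = E_HF + E_corr -- the defining identity."""
    eng = request.getfixturevalue(engine)
    scf, mp2, g = eng.scf, eng.mp2, eng.g
    r1, r2 = m.relaxed_densities(scf, mp2, g)
    c = scf.orbital_coefficients
    h_mo = c.T @ scf.integrals.hcore @ c
    e = (np.sum(h_mo * r1.spin_summed) + r2.vee(g).total
         + scf.integrals.nuclear_repulsion)
    assert e == pytest.approx(scf.e_hf + mp2.e_corr, abs=5e-8)
    assert sum(r1.trace()) == pytest.approx(scf.molecule.n_electrons, abs=1e-8)


def test_relaxed_density_is_the_energy_response(h2o_sto3g):
    """Finite-field check: tr(D w) equals dE_MP2/dlambda for h -> h + lw."""
    scf, mp2 = h2o_sto3g.scf, h2o_sto3g.mp2
    r1, _ = m.relaxed_densities(scf, mp2, h2o_sto3g.g)
    gen = np.random.default_rng(4)
    w = gen.standard_normal((scf.n_basis,) * 2)
    w = 0.05 * (w + w.T)
    dl = 2e-4
    es = []
    for lam in (dl, -dl):
        ints = copy.copy(scf.integrals)
        ints.kinetic = scf.integrals.kinetic + lam * w
        pert = run_rhf(scf.molecule, scf.basis_label, integrals=ints,
                       e_conv=1e-12)
        es.append(pert.e_hf + m.mp2_components(pert).e_corr)
    numeric = (es[0] - es[1]) / (2 * dl)
    c = scf.orbital_coefficients
    analytic = np.sum((c.T @ w @ c) * r1.spin_summed)
    assert numeric == pytest.approx(analytic, abs=5e-7)


def test_relaxed_vee_is_the_eri_scaling_response(h2_dz):
    """Vee from the relaxed 2-RDM equals dE/dl under (pq|rs) -> (1+l)(pq|rs)."""
    scf, mp2 = h2_dz.scf, h2_dz.mp2
    _, r2 = m.relaxed_densities(scf, mp2, h2_dz.g)
    dl = 2e-4
    es = []
    for lam in (dl, -dl):
        ints = copy.copy(scf.integrals)
        ints.eri = scf.integrals.eri * (1.0 + lam)
        pert = run_rhf(scf.molecule, scf.basis_label, integrals=ints,
                       e_conv=1e-12)
        es.append(pert.e_hf + m.mp2_components(pert).e_corr)
    numeric = (es[0] - es[1]) / (2 * dl)
    assert numeric == pytest.approx(r2.vee(h2_dz.g).total, abs=2e-5)


def test_degenerate_virtual_space_raises():
    from cdscs.molecule import Molecule

    mol = Molecule(("He",), np.zeros((1, 3)), name="he")
    scf = run_rhf(mol, "sto-3g")     # single basis function, no virtuals
    with pytest.raises(m.DegenerateInputError):
        m.mp2_components(scf)
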