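"""Scaling model: presets, coefficient evaluation, energies, error surfaces."""

import numpy as np
import pytest

from cdscs.indices import CorrelationIndices
from cdscs.scaling import (PRESETS, ScalingParams, SpeciesEnergies,
                           assemble_energy, coefficients, error_surface,
                           preset, zero_locus_slope)


def idx_for(r_d):
    return CorrelationIndices(1 - r_d, r_d, 1.0, r_d, 1 - r_d, 0.0)


def test_preset_registry_reproduces_published_coefficients():
    expected = {
        "mp2": (0.0, 0.0, 1.0, 1.0),
        "scs": (0.0, 0.0, 0.33, 1.2),
        "scs-star": (0.0, 0.0, 0.44, 1.13),
        "s2opt": (0.0, 0.0, 0.623, 1.055),
        "cd2": (2.89, 1.38, 0.0, 0.0),
        "cd4": (0.0, 0.42, 0.47, 0.79),
    }
    assert set(PRESETS) == set(expected)
    for name, (a, ap, b, bp) in expected.items():
        p = preset(name)
        assert (p.a, p.ap, p.b, p.bp) == (a, ap, b, bp)


@pytest.mark.parametrize("r_d,c_os,c_ss", [
    (1.0, 1.21, 0.47),      # top of the published c_OS interval
    (0.0, 0.79, 0.47),      # bottom of the interval
    (0.5, 1.00, 0.47),
])
def test_cd4_coefficients(r_d, c_os, c_ss):
    got = coefficients(preset("cd4"), idx_for(r_d))
    assert got[0] == pytest.approx(c_os, abs=1e-12)
    assert got[1] == pytest.approx(c_ss, abs=1e-12)


def test_cd2_coefficients_follow_footnote_assignment():
    c_os, c_ss = coefficients(preset("cd2"), idx_for(1.0))
    assert (c_os, c_ss) == (1.38, 0.0)
    c_os, c_ss = coefficients(preset("cd2"), idx_for(0.0))
    assert (c_os, c_ss) == (0.0, 2.89)


def test_index_dependent_model_requires_indices():
    with pytest.raises(ValueError):
        coefficients(preset("cd2"), None)
    assert coefficients(preset("scs"), None) == (1.2, 0.33)


def test_identity_scaling_reproduces_canonical_mp2():
    sp = SpeciesEnergies(-76.0, -0.2, -0.07)
    assert assemble_energy(sp, preset("mp2")) == pytest.approx(-76.27)


def test_grimme_scaling_of_the_h2_hole_contribution():
    """c_OS = 1.2 on an OS-only correlation of -0.051 au gives -0.0612 au."""
    sp = SpeciesEnergies(0.0, -0.051, 0.0)
    assert assemble_energy(sp, preset("scs")) == pytest.approx(-0.0612,
                                                               abs=1e-12)


def test_fixed_coefficient_degeneracy_of_the_cd_form():
    """a = a' = 0 makes the model species-independent."""
    params = ScalingParams(0.0, 0.0, 0.44, 1.13)
    sp = SpeciesEnergies(-1.0, -0.1, -0.03, idx_for(0.37))
    via_indices = assemble_energy(sp, params)
    sp_no_idx = SpeciesEnergies(-1.0, -0.1, -0.03)
    assert via_indices == pytest.approx(assemble_energy(sp_no_idx, params),
                                        abs=1e-15)


def test_energy_affine_in_parameters():
    sp = SpeciesEnergies(-1.0, -0.3, -0.1, idx_for(0.7))
    vals = {}
    for scale in (0.0, 1.0, 2.0):
        p = ScalingParams(0.2 * scale, 0.3 * scale, 0.1 * scale, 0.5 * scale)
        vals[scale] = assemble_energy(sp, p)
    assert vals[2.0] - vals[1.0] == pytest.approx(vals[1.0] - vals[0.0],
                                                  abs=1e-12)


class TestErrorSurface:
    species = {
        "A": SpeciesEnergies(-10.0, -0.30, -0.10),
        "B": SpeciesEnergies(-5.0, -0.12, -0.04),
        "C": SpeciesEnergies(-5.2, -0.20, -0.05),
    }
    stoich = {"A": -1.0, "B": 1.0, "C": 1.0}

    def test_zero_locus_is_the_analytic_line(self):
        """The exact-zero set is straight with slope -(sum nu E_OS)/(sum nu E_SS)."""
        d_hf = sum(nu * self.species[s].e_hf for s, nu in self.stoich.items())
        d_os = sum(nu * self.species[s].e_os for s, nu in self.stoich.items())
        d_ss = sum(nu * self.species[s].e_ss for s, nu in self.stoich.items())
        c_os0, c_ss0 = 1.1, 0.6
        ref = (d_hf + c_os0 * d_os + c_ss0 * d_ss) * 627.509474
        slope = zero_locus_slope(self.stoich, self.species)
        assert slope == pytest.approx(-d_os / d_ss, abs=1e-15)
        # moving along (1, slope) keeps the error identically zero ...
        for step in (0.0, 0.2, 0.5, -0.3):
            e = error_surface(self.stoich, ref, self.species,
                              np.array([c_os0 + step]),
                              np.array([c_ss0 + slope * step]))
            assert abs(e[0, 0]) < 1e-8
        # ... while leaving the line does not
        off = error_surface(self.stoich, ref, self.species,
                            np.array([c_os0 + 0.2]),
                            np.array([c_ss0 + slope * 0.2 + 0.1]))
        assert off[0, 0] > 1e-3

    def test_surface_independent_of_css_when_ss_cancels(self):
        species = {"A": SpeciesEnergies(-1.0, -0.2, -0.05),
                   "B": SpeciesEnergies(-2.0, -0.3, -0.05)}
        stoich = {"A": -2.0, "B": 1.0}      # sum nu E_SS = ... not zero
        species["B"] = SpeciesEnergies(-2.0, -0.3, -0.10)   # now 2*(-0.05)=-0.10
        grid_os = np.linspace(0, 2.5, 11)
        grid_ss = np.linspace(0, 2.5, 11)
        surf = error_surface(stoich, 3.0, species, grid_os, grid_ss)
        assert np.max(np.abs(surf - surf[:, :1])) < 1e-12

    def test_constructed_reaction_minimizes_at_grimme_point(self):
        """A reaction made exact at (1.2, 0.33) has its grid minimum there."""
        ref = (sum(nu * (sp.e_hf + 1.2 * sp.e_os + 0.33 * sp.e_ss)
                   for (s, nu), sp in zip(self.stoich.items(),
                                          [self.species[k] for k in self.stoich]))
               * 627.509474)
        grid_os = np.arange(0.0, 2.5001, 0.05)
        grid_ss = np.arange(0.03, 2.5301, 0.05)   # puts 0.33 on the grid
        surf = error_surface(self.stoich, ref, self.species, grid_os, grid_ss)
        i = int(np.argmin(np.abs(grid_os - 1.2)))
        j = int(np.argmin(np.abs(grid_ss - 0.33)))
        # the Grimme cell is an exact zero and hence a global grid minimum
        # (the zero locus is a line, so the minimizer need not be unique)
        assert surf[i, j] < 1e-9
        assert surf[i, j] == pytest.approx(surf.min(), abs=1e-9)
        ioff, joff = np.unravel_index(np.argmin(surf), surf.shape)
        slope = zero_locus_slope(self.stoich, self.species)
        assert grid_ss[joff] - 0.33 == pytest.approx(
            slope * (grid_os[ioff] - 1.2), abs=0.06)

    def test_unknown_species_raises(self):
        with pytest.raises(KeyError, match="unknown species"):
            error_surface({"Z": 1.0, "A": -1.0}, 0.0, self.species,
                          np.array([1.0]), np.array([1.0]))
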