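"""Shared fixtures: converged wavefunctions on the small named geometries.

Everything expensive is session-scoped; the first SCF also pays the numba
compilation of the integral kernels.
"""

import numpy as np
import pytest

from cdscs import mp2 as mp2mod
from cdscs.fci import fci_solve
from cdscs.molecule import fixture
from cdscs.scf import run_rhf


class Engine:
    """Lazily computed bundle (scf, mo eri, mp2, fci) for one system."""

    def __init__(self, name, basis):
        self.molecule = fixture(name)
        self.scf = run_rhf(self.molecule, basis)
        self._g = None
        self._mp2 = None
        self._fci = None

    @property
    def g(self):
        if self._g is None:
            self._g = mp2mod.mo_eri(self.scf)
        return self._g

    @property
    def mp2(self):
        if self._mp2 is None:
            self._mp2 = mp2mod.mp2_components(self.scf)
        return self._mp2

    @property
    def fci(self):
        if self._fci is None:
            self._fci = fci_solve(self.scf)
        return self._fci


@pytest.fixture(scope="session")
def h2_sto3g():
    return Engine("h2", "sto-3g")


@pytest.fixture(scope="session")
def h2_dz():
    return Engine("h2", "cc-pvdz")


@pytest.fixture(scope="session")
def h2_tz():
    return Engine("h2", "cc-pvtz")


@pytest.fixture(scope="session")
def he_dz():
    return Engine("he", "cc-pvdz")


@pytest.fixture(scope="session")
def he2_dz():
    return Engine("he2", "cc-pvdz")


@pytest.fixture(scope="session")
def h2o_sto3g():
    return Engine("h2o", "sto-3g")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
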