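"""Molecular geometries: the ``Molecule`` container, XYZ I/O and named fixtures.

Coordinates are stored in Angstrom (the XYZ convention); the integral layer
converts to bohr internally.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_TO_BOHR, NUCLEAR_CHARGE

__all__ = ["Molecule", "read_xyz", "write_xyz", "fixture", "FIXTURES"]


@dataclasses.dataclass(frozen=True)
class Molecule:
    """A molecular geometry with charge and spin multiplicity.

    Parameters
    ----------
    atoms
        Element symbols, e.g. ``("H", "H")``.
    coordinates
        ``(n_atoms, 3)`` Cartesian coordinates in Angstrom.
    charge
        Total charge.
    multiplicity
        Spin multiplicity 2S+1.  The built-in engine handles closed-shell
        singlets only.
    """

    atoms: tuple[str, ...]
    coordinates: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(len(self.atoms), 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "coordinates", coords)
        for el in self.atoms:
            if el not in NUCLEAR_CHARGE:
                raise ValueError(f"unsupported element {el!r}")

    @property
    def n_electrons(self) -> int:
        return sum(NUCLEAR_CHARGE[el] for el in self.atoms) - self.charge

    @property
    def nuclear_charges(self) -> np.ndarray:
        return np.array([NUCLEAR_CHARGE[el] for el in self.atoms], dtype=float)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coordinates * ANGSTROM_TO_BOHR

    def nuclear_repulsion(self) -> float:
        """Nuclear repulsion energy in hartree."""
        z = self.nuclear_charges
        r = self.coords_bohr
        e = 0.0
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e


def read_xyz(path: str | Path, charge: int = 0, multiplicity: int = 1) -> Molecule:
    """Read a standard XYZ file (count line, comment line, element x y z in A)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    atoms, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        atoms.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    return Molecule(tuple(atoms), np.array(coords), charge, multiplicity,
                    name=lines[1].strip() or Path(path).stem)


def write_xyz(molecule: Molecule, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(molecule.atoms)}\n{molecule.name}\n")
        for el, (x, y, z) in zip(molecule.atoms, molecule.coordinates):
            fh.write(f"{el} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def _diatomic(name, el1, el2, r_angstrom):
    return Molecule((el1, el2), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_angstrom]]),
                    name=name)


#: Named geometry fixtures (experimental equilibrium bond lengths, Angstrom).
#: ``lih_stretched`` is twice the LiH equilibrium distance; ``he2`` uses
#: 2.97 A, near the potential minimum of the helium-dimer dispersion well.
FIXTURES = {
    "h2": _diatomic("h2", "H", "H", 0.7414),
    "lih": _diatomic("lih", "Li", "H", 1.5957),
    "lih_stretched": _diatomic("lih_stretched", "Li", "H", 2 * 1.5957),
    "he2": _diatomic("he2", "He", "He", 2.97),
    "he": Molecule(("He",), np.zeros((1, 3)), name="he"),
    "h2o": Molecule(
        ("O", "H", "H"),
        np.array([[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]]),
        name="h2o",
    ),
}


def fixture(name: str) -> Molecule:
    """Return a named built-in geometry (h2, lih, lih_stretched, he2, he, h2o)."""
    try:
        return FIXTURES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
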