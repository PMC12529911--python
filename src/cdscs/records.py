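"""Interchange records: per-species energy components and reaction sets.

The species record is the package's data currency: everything the scaling
model needs about a molecule (HF energy, spin-resolved MP2 components,
natural occupancies) in a flat JSON-friendly form, whether produced by the
built-in engine or by an external program.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .indices import CorrelationIndices, OccupancySpectrum, indices

__all__ = ["SpeciesRecord", "compute_record", "load_record", "save_record",
           "load_occupancy_csv"]


@dataclasses.dataclass
class SpeciesRecord:
    label: str
    e_hf: float                       # hartree
    e_os: float                       # hartree, <= 0
    e_ss: float                       # hartree, <= 0
    occupancies: OccupancySpectrum | None
    basis: str = ""
    frozen_core: bool = False

    def __post_init__(self):
        if self.e_os > 1e-12 or self.e_ss > 1e-12:
            raise ValueError(
                f"{self.label}: correlation components must be non-positive "
                f"(E_OS={self.e_os}, E_SS={self.e_ss})")

    def correlation_indices(self) -> CorrelationIndices:
        if self.occupancies is None:
            raise ValueError(f"{self.label}: record carries no occupancies")
        return indices(self.occupancies)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "E_HF_hartree": self.e_hf,
            "E_OS_hartree": self.e_os,
            "E_SS_hartree": self.e_ss,
            "basis": self.basis,
            "frozen_core": self.frozen_core,
        }
        if self.occupancies is not None:
            d["occupancies"] = {
                "alpha": [float(x) for x in self.occupancies.alpha],
                "beta": [float(x) for x in self.occupancies.beta],
                "n_electrons": self.occupancies.n_electrons,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesRecord":
        occ = None
        if "occupancies" in d and d["occupancies"] is not None:
            o = d["occupancies"]
            n = o.get("n_electrons")
            if n is None:
                n = float(np.sum(o["alpha"]) + np.sum(o["beta"]))
            occ = OccupancySpectrum(np.asarray(o["alpha"], float),
                                    np.asarray(o["beta"], float), n)
        return cls(d["label"], d["E_HF_hartree"], d["E_OS_hartree"],
                   d["E_SS_hartree"], occ, d.get("basis", ""),
                   d.get("frozen_core", False))


def compute_record(molecule, basis: str, frozen_core: bool = False,
                   label: str | None = None) -> SpeciesRecord:
    """Run the built-in engine (RHF + MP2) and package the result."""
    from .mp2 import mp2_components, unrelaxed_occupancies
    from .scf import run_rhf

    scf = run_rhf(molecule, basis)
    mp2 = mp2_components(scf, frozen_core=frozen_core)
    spectrum = unrelaxed_occupancies(scf, mp2)
    return SpeciesRecord(label or molecule.name or "species",
                         scf.e_hf, mp2.e_os, mp2.e_ss, spectrum,
                         basis=basis, frozen_core=frozen_core)


def save_record(record: SpeciesRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record.to_dict(), indent=1, sort_keys=True))


def load_record(path: str | Path) -> SpeciesRecord:
    return SpeciesRecord.from_dict(json.loads(Path(path).read_text()))


def load_occupancy_csv(path: str | Path, n_electrons: float | None = None
                       ) -> OccupancySpectrum:
    """Bare occupancy list: one value per line; 'alpha'/'beta' section headers.

    Without headers all values go to the alpha channel.
    """
    current = "alpha"
    chans: dict[str, list[float]] = {"alpha": [], "beta": []}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() in chans:
            current = line.lower()
            continue
        chans[current].append(float(line))
    if n_electrons is None:
        n_electrons = float(np.sum(chans["alpha"]) + np.sum(chans["beta"]))
    return OccupancySpectrum(np.asarray(chans["alpha"]),
                             np.asarray(chans["beta"]), n_electrons)
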