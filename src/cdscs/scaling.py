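"""Correlation-driven spin-component scaling of the MP2 energy.

The scaled total energy of a species is

    E = E_HF + c_OS E_OS + c_SS E_SS

with coefficients set per species from its correlation-index ratios:

    c_SS = a  * r_ND + b        (r_ND = I_ND / I_T)
    c_OS = a' * r_D  + b'       (r_D  = I_D  / I_T)

Fixed-coefficient variants (canonical MP2, Grimme's SCS-MP2, ...) are the
degenerate case a = a' = 0.  Coefficients are never clipped: intervals such
as c_OS in [0.79, 1.21] for the four-parameter model emerge from r_D in
[0, 1].
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .constants import HARTREE_TO_KCAL
from .indices import CorrelationIndices

__all__ = ["ScalingParams", "SpeciesEnergies", "PRESETS", "preset",
           "coefficients", "assemble_energy", "reaction_model_energy",
           "error_surface", "zero_locus_slope"]


@dataclasses.dataclass(frozen=True)
class ScalingParams:
    """(a, a', b, b') of the linear coefficient model; see module docstring."""

    a: float
    ap: float
    b: float
    bp: float
    name: str = ""

    @property
    def is_fixed(self) -> bool:
        return self.a == 0.0 and self.ap == 0.0

    def as_dict(self) -> dict:
        return {"a": self.a, "ap": self.ap, "b": self.b, "bp": self.bp,
                "name": self.name}


#: Published coefficient sets.  The two correlation-driven models follow the
#: table-footnote assignment c_OS = a'(I_D/I_T) + b', c_SS = a(I_ND/I_T) + b.
PRESETS: dict[str, ScalingParams] = {
    "mp2": ScalingParams(0.0, 0.0, 1.0, 1.0, "mp2"),
    "scs": ScalingParams(0.0, 0.0, 0.33, 1.2, "scs"),
    "scs-star": ScalingParams(0.0, 0.0, 0.44, 1.13, "scs-star"),
    "s2opt": ScalingParams(0.0, 0.0, 0.623, 1.055, "s2opt"),
    "cd2": ScalingParams(2.89, 1.38, 0.0, 0.0, "cd2"),
    "cd4": ScalingParams(0.0, 0.42, 0.47, 0.79, "cd4"),
}


def preset(name: str) -> ScalingParams:
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}"
                       ) from None


@dataclasses.dataclass
class SpeciesEnergies:
    """Energy components of one species (hartree) plus optional indices."""

    e_hf: float
    e_os: float
    e_ss: float
    indices: CorrelationIndices | None = None

    def __post_init__(self):
        if self.e_os > 1e-12 or self.e_ss > 1e-12:
            raise ValueError("correlation components must be non-positive")


def coefficients(params: ScalingParams,
                 idx: CorrelationIndices | None = None) -> tuple[float, float]:
    """(c_OS, c_SS) for one species.

    Indices are required whenever the model is correlation-driven
    (a or a' nonzero).
    """
    if idx is None:
        if not params.is_fixed:
            raise ValueError(
                f"model {params.name or params} has index-dependent "
                "coefficients but no correlation indices were given")
        return params.bp, params.b
    return params.ap * idx.r_d + params.bp, params.a * idx.r_nd + params.b


def assemble_energy(species: SpeciesEnergies, params: ScalingParams) -> float:
    """Scaled total energy E_HF + c_OS E_OS + c_SS E_SS (hartree)."""
    c_os, c_ss = coefficients(params, species.indices)
    return species.e_hf + c_os * species.e_os + c_ss * species.e_ss


def reaction_model_energy(stoichiometry: dict[str, float],
                          species: dict[str, SpeciesEnergies],
                          params: ScalingParams) -> float:
    """Reaction energy (kcal/mol) with per-species coefficients."""
    try:
        total = sum(nu * assemble_energy(species[label], params)
                    for label, nu in stoichiometry.items())
    except KeyError as exc:
        raise KeyError(f"reaction references unknown species {exc}") from None
    return total * HARTREE_TO_KCAL


def error_surface(stoichiometry: dict[str, float], reference_kcal: float,
                  species: dict[str, SpeciesEnergies],
                  c_os_grid: np.ndarray, c_ss_grid: np.ndarray) -> np.ndarray:
    """|error| (kcal/mol) over a (c_OS, c_SS) grid of uniform fixed scalings.

    Rows follow ``c_os_grid``, columns ``c_ss_grid``.  The reaction energy is
    affine in (c_OS, c_SS), so the zero locus is the straight line
    c_SS = -(sum nu E_OS / sum nu E_SS) c_OS + const.
    """
    try:
        d_hf = sum(nu * species[s].e_hf for s, nu in stoichiometry.items())
        d_os = sum(nu * species[s].e_os for s, nu in stoichiometry.items())
        d_ss = sum(nu * species[s].e_ss for s, nu in stoichiometry.items())
    except KeyError as exc:
        raise KeyError(f"reaction references unknown species {exc}") from None
    e = (d_hf + np.asarray(c_os_grid)[:, None] * d_os
         + np.asarray(c_ss_grid)[None, :] * d_ss) * HARTREE_TO_KCAL
    return np.abs(e - reference_kcal)


def zero_locus_slope(stoichiometry: dict[str, float],
                     species: dict[str, SpeciesEnergies]) -> float:
    """Slope dc_SS/dc_OS of the exact-zero line of the error surface."""
    d_os = sum(nu * species[s].e_os for s, nu in stoichiometry.items())
    d_ss = sum(nu * species[s].e_ss for s, nu in stoichiometry.items())
    if d_ss == 0.0:
        raise ZeroDivisionError("surface is independent of c_SS")
    return -d_os / d_ss
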