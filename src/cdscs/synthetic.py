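"""Synthetic species records and reaction sets for testing the pipeline.

The generator emulates the *shape* of benchmark data -- energy components
with realistic magnitudes, occupancy spectra with a prescribed dynamic
fraction r_D, reference energies from a known ground-truth scaling model plus
Gaussian noise -- without pretending to be any real benchmark set.

Occupancy spectra come from a two-pair family on top of an idempotent core:
a weakly split pair (dynamic character) and a strongly split pair
(nondynamic character), with splits sqrt(n(1-n)) = (s^2/2, s/2) driven by a
single knob s in (0, 1].  The resulting nondynamic fraction

    r_ND(s) = s (s^2 + 1) / (s + 1)

is strictly increasing with r_ND(1) = 1 (both pairs at 0.5/0.5), so any
target r_D in [0, 1) is reached by a bracketing root solve; r_D = 1 maps to
the idempotent spectrum handled by the I_T -> 0 convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .benchmark import Reaction, ReactionSet
from .indices import OccupancySpectrum, indices
from .records import SpeciesRecord
from .scaling import ScalingParams, SpeciesEnergies, reaction_model_energy

__all__ = ["SyntheticSpec", "spectrum_for_rd", "gen_species", "gen_reactions",
           "GenerationError"]


class GenerationError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark generator.

    Magnitude ranges are hartree and bracket typical small main-group
    molecules (HF energies tens of hartree; opposite-spin correlation a few
    tenths; same-spin roughly a third of that).  ``noise_sigma`` is the
    Gaussian noise (kcal/mol) on the reference energies.
    """

    n_species: int = 40
    r_d_range: tuple[float, float] = (0.55, 0.99)
    e_hf_range: tuple[float, float] = (-120.0, -20.0)
    e_os_range: tuple[float, float] = (-1.2, -0.2)
    e_ss_range: tuple[float, float] = (-0.45, -0.05)
    params: ScalingParams = dataclasses.field(
        default_factory=lambda: ScalingParams(0.0, 0.42, 0.47, 0.79, "cd4"))
    noise_sigma: float = 1.0
    seed: int = 2026
    core_orbitals: int = 3

    def __post_init__(self):
        lo, hi = self.r_d_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise GenerationError("r_D range must lie within [0, 1]")
        if self.noise_sigma < 0:
            raise GenerationError("noise sigma must be nonnegative")
        if self.seed is None:
            raise GenerationError("a seed is mandatory")


def _rnd_of_s(s: float) -> float:
    return s * (s * s + 1.0) / (s + 1.0)


def _split_to_occupancy(u: float) -> float:
    """Occupancy n <= 1/2 with sqrt(n(1-n)) = u."""
    if u > 0.5 + 1e-12:
        raise GenerationError(f"unreachable split {u}")
    return 0.5 * (1.0 - np.sqrt(max(1.0 - 4.0 * u * u, 0.0)))


def spectrum_for_rd(r_d: float, core_orbitals: int = 3) -> OccupancySpectrum:
    """Occupancy spectrum whose indices reproduce the target r_D to 1e-6."""
    if not 0.0 <= r_d <= 1.0:
        raise GenerationError(f"target r_D {r_d} outside [0, 1]")
    core = [1.0] * core_orbitals
    if r_d == 1.0:
        chan = np.array(core + [1.0, 1.0, 0.0, 0.0])
    else:
        s = brentq(lambda t: _rnd_of_s(t) - (1.0 - r_d), 1e-12, 1.0,
                   xtol=1e-15, rtol=8.9e-16)
        x = _split_to_occupancy(0.5 * s * s)   # weak (dynamic) pair
        y = _split_to_occupancy(0.5 * s)       # strong (nondynamic) pair
        chan = np.array(core + [1.0 - x, 1.0 - y, y, x])
    n = 2.0 * (core_orbitals + 2)
    return OccupancySpectrum(chan.copy(), chan.copy(), n)


def gen_species(spec: SyntheticSpec) -> list[SpeciesRecord]:
    """Deterministic batch of synthetic species records."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_species):
        r_d = rng.uniform(*spec.r_d_range)
        occ = spectrum_for_rd(r_d, spec.core_orbitals)
        achieved = indices(occ).r_d
        if abs(achieved - r_d) > 1e-6:
            raise GenerationError(
                f"round-trip failure: target r_D {r_d}, got {achieved}")
        rec = SpeciesRecord(
            label=f"syn{i:04d}",
            e_hf=rng.uniform(*spec.e_hf_range),
            e_os=rng.uniform(*spec.e_os_range),
            e_ss=rng.uniform(*spec.e_ss_range),
            occupancies=occ,
            basis="synthetic",
        )
        out.append(rec)
    return out


def gen_reactions(species: list[SpeciesRecord], params: ScalingParams,
                  noise_sigma: float, seed: int, n_reactions: int = 60,
                  subset_names: tuple[str, ...] = ("S1", "S2", "S3"),
                  rng: np.random.Generator | None = None) -> ReactionSet:
    """Reactions with references = ground-truth model energies + noise."""
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = {rec.label: rec for rec in species}
    comp = {label: SpeciesEnergies(rec.e_hf, rec.e_os, rec.e_ss,
                                   rec.correlation_indices())
            for label, rec in pool.items()}
    labels = list(pool)
    reactions = []
    for k in range(n_reactions):
        n_spc = int(rng.integers(2, 5))
        chosen = rng.choice(labels, size=n_spc, replace=False)
        nus = rng.choice([-2.0, -1.0, 1.0, 2.0], size=n_spc)
        nus[0] = abs(nus[0])
        nus[1] = -abs(nus[1])
        stoich = {str(s): float(nu) for s, nu in zip(chosen, nus)}
        ref = reaction_model_energy(stoich, comp, params)
        ref += rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        reactions.append(Reaction(f"rx{k:04d}",
                                  subset_names[k % len(subset_names)],
                                  stoich, ref))
    return ReactionSet(pool, reactions)
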