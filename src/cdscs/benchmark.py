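"""Reaction-energy benchmarks: error statistics and multireference screening.

Statistics follow the thermochemistry-benchmark conventions: MAD (mean
absolute deviation), MAX, RMSD, and the weighted WTMAD2

    WTMAD2 = (1 / sum_i N_i) sum_i N_i * (56.84 / |dE|avg_i) * MAD_i

where subsets i carry N_i data points with mean absolute reference energy
|dE|avg_i; the 56.84 kcal/mol constant is the all-subset average of
|dE|avg_i in the reference benchmark and is configurable.  Signed errors are
computed - reference throughout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .constants import HARTREE_TO_KCAL, IND_MAX_THRESHOLD, WTMAD2_REFERENCE_KCAL
from .indices import CorrelationIndices
from .records import SpeciesRecord
from .scaling import ScalingParams, SpeciesEnergies, reaction_model_energy

__all__ = ["Reaction", "ReactionSet", "SubsetStats", "ErrorReport",
           "reaction_energy", "error_stats", "multiref_filter", "evaluate",
           "load_reaction_set", "save_reaction_set"]


@dataclasses.dataclass
class Reaction:
    id: str
    subset: str
    stoichiometry: dict[str, float]
    reference_kcal: float

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        # atomization-style single-species entries are allowed; a
        # multi-species reaction needs both products and reactants
        signs = {np.sign(v) for v in self.stoichiometry.values()}
        if len(self.stoichiometry) > 1 and len(signs - {0.0}) < 2:
            raise ValueError(
                f"reaction {self.id}: needs both positive and negative "
                "coefficients")


@dataclasses.dataclass
class ReactionSet:
    species: dict[str, SpeciesRecord]
    reactions: list[Reaction]
    subset_de_avg: dict[str, float] = dataclasses.field(default_factory=dict)
    subset_groups: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    def subsets(self) -> list[str]:
        return sorted({r.subset for r in self.reactions})

    def restrict(self, reactions: list[Reaction]) -> "ReactionSet":
        return ReactionSet(self.species, list(reactions), dict(self.subset_de_avg),
                           dict(self.subset_groups))

    def exclude_groups(self, names: list[str]) -> "ReactionSet":
        """Drop reactions whose subset belongs to any named subset group."""
        drop = set()
        for n in names:
            drop.update(self.subset_groups.get(n, [n]))
        return self.restrict([r for r in self.reactions if r.subset not in drop])


@dataclasses.dataclass
class SubsetStats:
    name: str
    n: int
    mad: float
    de_avg: float


@dataclasses.dataclass
class ErrorReport:
    mad: float
    max: float
    rmsd: float
    wtmad2: float
    subsets: list[SubsetStats]

    def to_csv(self, path: str | Path) -> None:
        lines = ["statistic,kcal_per_mol",
                 f"MAD,{self.mad:.6f}", f"MAX,{self.max:.6f}",
                 f"RMSD,{self.rmsd:.6f}", f"WTMAD2,{self.wtmad2:.6f}",
                 "", "subset,N,MAD,dE_avg"]
        lines += [f"{s.name},{s.n},{s.mad:.6f},{s.de_avg:.6f}"
                  for s in self.subsets]
        Path(path).write_text("\n".join(lines) + "\n")


def reaction_energy(reaction: Reaction,
                    energies_hartree: dict[str, float]) -> float:
    """sum nu E (hartree) converted to kcal/mol."""
    missing = [s for s in reaction.stoichiometry if s not in energies_hartree]
    if missing:
        raise KeyError(f"reaction {reaction.id}: missing species {missing}")
    total = sum(nu * energies_hartree[s]
                for s, nu in reaction.stoichiometry.items())
    return total * HARTREE_TO_KCAL


def error_stats(errors: dict[str, float], subsets: dict[str, str],
                reference_kcal: dict[str, float],
                de_avg_override: dict[str, float] | None = None,
                wtmad2_constant: float = WTMAD2_REFERENCE_KCAL) -> ErrorReport:
    """Error statistics over signed errors (kcal/mol) keyed by reaction id.

    ``subsets`` maps reaction id -> subset name; ``reference_kcal`` supplies
    the reference energies from which per-subset |dE|avg is computed, unless
    a subset appears in ``de_avg_override`` (e.g. published full-set values).
    """
    if not errors:
        raise ValueError("no errors supplied: statistics undefined")
    vals = np.array([errors[k] for k in errors])
    ids = list(errors)
    mad = float(np.mean(np.abs(vals)))
    mx = float(np.max(np.abs(vals)))
    rmsd = float(np.sqrt(np.mean(vals ** 2)))
    by_subset: dict[str, list[str]] = {}
    for rid in ids:
        by_subset.setdefault(subsets[rid], []).append(rid)
    stats, wsum, ntot = [], 0.0, 0
    override = de_avg_override or {}
    for name in sorted(by_subset):
        members = by_subset[name]
        sub_mad = float(np.mean([abs(errors[r]) for r in members]))
        de_avg = override.get(
            name, float(np.mean([abs(reference_kcal[r]) for r in members])))
        if de_avg <= 0:
            raise ValueError(f"subset {name}: |dE|avg must be positive")
        stats.append(SubsetStats(name, len(members), sub_mad, de_avg))
        wsum += len(members) * (wtmad2_constant / de_avg) * sub_mad
        ntot += len(members)
    return ErrorReport(mad, mx, rmsd, wsum / ntot, stats)


def multiref_filter(indices_by_species: dict[str, CorrelationIndices],
                    reactions: list[Reaction],
                    threshold: float = IND_MAX_THRESHOLD
                    ) -> tuple[list[Reaction], dict[str, list[str]]]:
    """Drop reactions containing any species with I_ND^max above threshold.

    Returns the surviving reactions and a log {reaction id: flagged species}.
    """
    kept, log = [], {}
    for rxn in reactions:
        missing = [s for s in rxn.stoichiometry if s not in indices_by_species]
        if missing:
            raise ValueError(f"reaction {rxn.id}: no indices for {missing}")
        flagged = [s for s in rxn.stoichiometry
                   if indices_by_species[s].i_nd_max > threshold]
        if flagged:
            log[rxn.id] = flagged
        else:
            kept.append(rxn)
    return kept, log


def evaluate(rset: ReactionSet, params: ScalingParams,
             filter_multiref: float | None = None,
             de_avg_override: dict[str, float] | None = None,
             wtmad2_constant: float = WTMAD2_REFERENCE_KCAL) -> ErrorReport:
    """Score a scaling model on a reaction set (signed error = model - ref)."""
    species = {
        label: SpeciesEnergies(
            rec.e_hf, rec.e_os, rec.e_ss,
            rec.correlation_indices() if rec.occupancies is not None else None)
        for label, rec in rset.species.items()
    }
    reactions = rset.reactions
    if filter_multiref is not None:
        idx = {label: rec.correlation_indices()
               for label, rec in rset.species.items()}
        reactions, _ = multiref_filter(idx, reactions, filter_multiref)
    errors, subsets, refs = {}, {}, {}
    for rxn in reactions:
        model = reaction_model_energy(rxn.stoichiometry, species, params)
        errors[rxn.id] = model - rxn.reference_kcal
        subsets[rxn.id] = rxn.subset
        refs[rxn.id] = rxn.reference_kcal
    return error_stats(errors, subsets, refs, de_avg_override, wtmad2_constant)


def save_reaction_set(rset: ReactionSet, path: str | Path) -> None:
    d = {
        "species": [rec.to_dict() for rec in rset.species.values()],
        "reactions": [
            {"id": r.id, "subset": r.subset, "stoichiometry": r.stoichiometry,
             "reference_kcal": r.reference_kcal} for r in rset.reactions
        ],
        "subsets": [{"name": k, "dEavg": v} for k, v in rset.subset_de_avg.items()],
        "subset_groups": rset.subset_groups,
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def load_reaction_set(path: str | Path) -> ReactionSet:
    d = json.loads(Path(path).read_text())
    species = {}
    for entry in d.get("species", []):
        if isinstance(entry, str):
            from .records import load_record
            rec = load_record(Path(path).parent / entry)
        else:
            rec = SpeciesRecord.from_dict(entry)
        species[rec.label] = rec
    reactions = [Reaction(r["id"], r.get("subset", "all"),
                          {k: float(v) for k, v in r["stoichiometry"].items()},
                          float(r["reference_kcal"]))
                 for r in d.get("reactions", [])]
    de_avg = {s["name"]: float(s["dEavg"]) for s in d.get("subsets", [])
              if s.get("dEavg") is not None}
    return ReactionSet(species, reactions, de_avg, d.get("subset_groups", {}))
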