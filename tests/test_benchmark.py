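"""Benchmark statistics: reaction energies, WTMAD2, multireference screen."""

import numpy as np
import pytest

from cdscs.benchmark import (ErrorReport, Reaction, error_stats,
                             multiref_filter, reaction_energy)
from cdscs.constants import WTMAD2_REFERENCE_KCAL
from cdscs.indices import CorrelationIndices


def rxn(rid, stoich, ref=0.0, subset="s"):
    return Reaction(rid, subset, stoich, ref)


class TestReactionEnergy:
    def test_identity_reaction_cancels(self):
        assert reaction_energy(rxn("id", {"A": 1.0, "A2": -1.0}),
                               {"A": -3.7, "A2": -3.7}) == 0.0

    def test_hand_value_with_conversion_constant(self):
        r = rxn("form", {"H": -2.0, "H2": 1.0})
        e = reaction_energy(r, {"H": -0.5, "H2": -1.2})
        assert e == pytest.approx(-0.2 * 627.509474, abs=1e-9)

    def test_stoichiometry_order_irrelevant(self):
        en = {"A": -1.0, "B": -2.0, "C": -0.5}
        r1 = rxn("r", {"A": -1.0, "B": 1.0, "C": 2.0})
        r2 = rxn("r", {"C": 2.0, "A": -1.0, "B": 1.0})
        assert reaction_energy(r1, en) == reaction_energy(r2, en)

    def test_missing_species_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            reaction_energy(rxn("r", {"ghost": 1.0, "A": -1.0}), {"A": -1.0})

    def test_all_positive_multispecies_rejected(self):
        with pytest.raises(ValueError):
            Reaction("bad", "s", {"A": 1.0, "B": 2.0}, 0.0)


class TestErrorStats:
    def test_single_subset_with_unit_weight(self):
        errors = {"a": 1.0, "b": -3.0}
        refs = {"a": WTMAD2_REFERENCE_KCAL, "b": WTMAD2_REFERENCE_KCAL}
        rep = error_stats(errors, {"a": "s", "b": "s"}, refs)
        assert rep.wtmad2 == pytest.approx(rep.mad)
        assert rep.mad == pytest.approx(2.0)
        assert rep.max == pytest.approx(3.0)
        assert rep.rmsd == pytest.approx(np.sqrt(5.0))

    def test_two_subset_hand_value(self):
        """N=(2,3), MAD=(1,2), |dE|avg=(28.42,113.68) -> WTMAD2 = 1.4."""
        errors = {"a1": 1.0, "a2": -1.0, "b1": 2.0, "b2": 2.0, "b3": -2.0}
        subsets = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        refs = {"a1": 28.42, "a2": -28.42, "b1": 113.68, "b2": 113.68,
                "b3": -113.68}
        rep = error_stats(errors, subsets, refs)
        assert rep.wtmad2 == pytest.approx(1.4, abs=1e-12)

    def test_constant_magnitude_collapses_statistics(self):
        errors = {f"r{i}": (-1.0) ** i * 2.5 for i in range(7)}
        rep = error_stats(errors, {k: "s" for k in errors},
                          {k: 10.0 for k in errors})
        assert rep.mad == rep.max == rep.rmsd == pytest.approx(2.5)

    def test_max_bounds_mad(self, rng):
        errors = {f"r{i}": e for i, e in enumerate(rng.normal(size=50))}
        rep = error_stats(errors, {k: "s" for k in errors},
                          {k: 5.0 for k in errors})
        assert rep.max >= rep.mad >= 0
        assert isinstance(rep, ErrorReport)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no errors"):
            error_stats({}, {}, {})

    def test_wtmad2_matches_brute_force_double_loop(self, rng):
        """Oracle: explicit loop over data points, Eq-style weighting."""
        for trial in range(5):
            n = int(rng.integers(5, 40))
            subset_names = [f"S{i}" for i in range(int(rng.integers(1, 6)))]
            errors, subsets, refs = {}, {}, {}
            for i in range(n):
                rid = f"r{i}"
                errors[rid] = float(rng.normal(scale=3.0))
                subsets[rid] = str(rng.choice(subset_names))
                refs[rid] = float(rng.uniform(1.0, 200.0))
            rep = error_stats(errors, subsets, refs)
            # brute force
            names = sorted({subsets[r] for r in errors})
            total_n = 0
            acc = 0.0
            for s in names:
                members = [r for r in errors if subsets[r] == s]
                mad_i = sum(abs(errors[r]) for r in members) / len(members)
                de_i = sum(abs(refs[r]) for r in members) / len(members)
                acc += len(members) * (56.84 / de_i) * mad_i
                total_n += len(members)
            assert rep.wtmad2 == pytest.approx(acc / total_n, abs=1e-12)

    def test_reordering_invariance(self, rng):
        keys = [f"r{i}" for i in range(20)]
        errors = {k: float(rng.normal()) for k in keys}
        subsets = {k: f"S{i % 3}" for i, k in enumerate(keys)}
        refs = {k: float(rng.uniform(1, 50)) for k in keys}
        rep1 = error_stats(errors, subsets, refs)
        shuffled = list(keys)[::-1]
        rep2 = error_stats({k: errors[k] for k in shuffled}, subsets, refs)
        assert rep1.wtmad2 == pytest.approx(rep2.wtmad2, abs=1e-14)
        assert rep1.mad == pytest.approx(rep2.mad, abs=1e-14)

    def test_de_avg_override(self):
        errors = {"a": 1.0}
        rep = error_stats(errors, {"a": "s"}, {"a": 10.0},
                          de_avg_override={"s": 56.84})
        assert rep.wtmad2 == pytest.approx(1.0)


class TestMultirefFilter:
    clean = CorrelationIndices(0.01, 0.1, 0.11, 0.9, 0.1, 0.010)
    flagged = CorrelationIndices(0.2, 0.1, 0.3, 0.33, 0.67, 0.150)
    idx = {"ok1": clean, "ok2": clean, "bad": flagged}

    def reactions(self):
        return [
            rxn("r1", {"ok1": 1.0, "ok2": -1.0}),
            rxn("r2", {"ok1": 1.0, "bad": -1.0}),
            rxn("r3", {"ok2": 2.0, "ok1": -2.0}),
            rxn("r4", {"bad": 1.0, "ok2": -1.0}),
            rxn("r5", {"ok1": 1.0, "ok2": -2.0}),
        ]

    def test_two_of_five_reactions_dropped(self):
        kept, log = multiref_filter(self.idx, self.reactions(), 0.030)
        assert [r.id for r in kept] == ["r1", "r3", "r5"]
        assert set(log) == {"r2", "r4"}
        assert log["r2"] == ["bad"]

    def test_infinite_threshold_is_identity(self):
        kept, log = multiref_filter(self.idx, self.reactions(), np.inf)
        assert len(kept) == 5 and not log

    def test_zero_threshold_with_correlated_species_empties(self):
        kept, _ = multiref_filter(self.idx, self.reactions(), 0.0)
        assert kept == []

    def test_missing_indices_raise(self):
        with pytest.raises(ValueError, match="r1"):
            multiref_filter({"ok1": self.clean}, self.reactions()[:1])

    def test_filtered_statistics_use_recomputed_counts(self):
        kept, _ = multiref_filter(self.idx, self.reactions(), 0.030)
        errors = {r.id: 1.0 for r in kept}
        refs = {r.id: 10.0 for r in kept}
        rep = error_stats(errors, {r.id: "s" for r in kept}, refs)
        assert rep.subsets[0].n == 3
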