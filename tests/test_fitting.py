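"""Convex LAD fitting of the scaling parameters."""

import numpy as np
import pytest

from cdscs.fitting import FitSpec, RankDeficiencyWarning, fit, profile
from cdscs.scaling import ScalingParams, preset
from cdscs.synthetic import SyntheticSpec, gen_reactions, gen_species


def training_set(params, sigma=0.0, n_species=25, n_reactions=40, seed=11):
    spec = SyntheticSpec(n_species=n_species, params=params,
                         noise_sigma=sigma, seed=seed)
    sp = gen_species(spec)
    return gen_reactions(sp, params, sigma, seed + 1, n_reactions=n_reactions)


def test_exact_recovery_of_four_parameter_truth():
    truth = preset("cd4")          # a=0, ap=0.42, b=0.47, bp=0.79
    rset = training_set(truth)
    res = fit(rset, FitSpec())
    assert res.objective < 1e-6
    for attr in ("a", "ap", "b", "bp"):
        assert getattr(res.params, attr) == pytest.approx(
            getattr(truth, attr), abs=1e-6)
    assert res.objective <= res.objective_initial


def test_fixed_coefficient_pattern_recovers_scs_star():
    """Fix a = a' = 0; data from fixed (c_OS, c_SS) = (1.13, 0.44)."""
    truth = ScalingParams(0.0, 0.0, 0.44, 1.13, "scs-star")
    rset = training_set(truth)
    res = fit(rset, FitSpec(free=("b", "bp"), fixed={"a": 0.0, "ap": 0.0}))
    assert res.params.b == pytest.approx(0.44, abs=1e-6)
    assert res.params.bp == pytest.approx(1.13, abs=1e-6)


def test_two_parameter_pattern_recovers_cd2():
    truth = preset("cd2")
    rset = training_set(truth)
    res = fit(rset, FitSpec(free=("a", "ap"), fixed={"b": 0.0, "bp": 0.0}))
    assert res.params.a == pytest.approx(2.89, abs=1e-6)
    assert res.params.ap == pytest.approx(1.38, abs=1e-6)


def test_lp_agrees_with_derivative_free_multistart():
    rset = training_set(preset("cd4"), sigma=1.5)
    res = fit(rset, FitSpec(cross_check=True, seed=3))
    assert res.converged


def test_one_reaction_interpolates_with_warning():
    rset = training_set(preset("cd4"), sigma=2.0)
    rset = rset.restrict(rset.reactions[:1])
    with pytest.warns(RankDeficiencyWarning):
        res = fit(rset, FitSpec())
    assert res.objective < 1e-9
    assert res.null_directions


def test_objective_convex_along_random_segments(rng):
    from cdscs.fitting import design_matrix

    rset = training_set(preset("cd4"), sigma=1.0)
    m, c = design_matrix(rset)
    for _ in range(25):
        t1 = rng.normal(size=4)
        t2 = rng.normal(size=4)
        f = lambda t: np.mean(np.abs(c + m @ t))
        mid = f(0.5 * (t1 + t2))
        assert mid <= 0.5 * (f(t1) + f(t2)) + 1e-12


def test_fit_invariant_under_reaction_relabeling():
    rset = training_set(preset("cd4"), sigma=1.0)
    res1 = fit(rset, FitSpec())
    reordered = rset.restrict(rset.reactions[::-1])
    res2 = fit(reordered, FitSpec())
    assert res1.objective == pytest.approx(res2.objective, abs=1e-9)
    assert res1.params.ap == pytest.approx(res2.params.ap, abs=1e-6)


def test_noise_consistency_estimates_approach_truth():
    """Parameter error shrinks as the training set grows (fixed seed)."""
    truth = ScalingParams(0.0, 0.0, 0.44, 1.13)
    errs = []
    for n in (30, 100, 300):
        rset = training_set(truth, sigma=1.0, n_species=40, n_reactions=n,
                            seed=5)
        res = fit(rset, FitSpec(free=("b", "bp"), fixed={"a": 0, "ap": 0}))
        errs.append(abs(res.params.b - 0.44) + abs(res.params.bp - 1.13))
    assert errs[2] < errs[0]
    assert errs[2] < 0.02


class TestProfile:
    def test_optimum_not_above_grid(self):
        rset = training_set(preset("cd4"), sigma=1.0)
        spec = FitSpec()
        res = fit(rset, spec)
        g = np.linspace(0.0, 1.5, 16)
        surf = profile(rset, spec, ("b", "bp"), (g, g), at=res.params)
        assert res.objective <= surf.min() + 1e-9

    def test_single_valley_for_fixed_coefficient_data(self):
        truth = ScalingParams(0.0, 0.0, 0.44, 1.13)
        rset = training_set(truth)
        spec = FitSpec(free=("b", "bp"), fixed={"a": 0.0, "ap": 0.0})
        gb = np.linspace(0.0, 1.0, 21)
        gbp = np.linspace(0.5, 1.7, 25)
        surf = profile(rset, spec, ("b", "bp"), (gb, gbp))
        i, j = np.unravel_index(np.argmin(surf), surf.shape)
        # minimum sits at the grid point nearest the truth
        assert gb[i] == pytest.approx(0.45, abs=0.051)
        assert gbp[j] == pytest.approx(1.13, abs=0.051)

    def test_scanning_fixed_parameter_is_an_error(self):
        rset = training_set(preset("cd4"))
        spec = FitSpec(free=("b", "bp"), fixed={"a": 0.0, "ap": 0.0})
        with pytest.raises(ValueError, match="fixed parameter"):
            profile(rset, spec, ("a", "b"),
                    (np.zeros(2), np.zeros(2)))


def test_spec_validation():
    with pytest.raises(ValueError):
        FitSpec(free=())
    with pytest.raises(ValueError):
        FitSpec(free=("a",), fixed={"a": 1.0})
    with pytest.raises(ValueError):
        FitSpec(objective="wtmad2")
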