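"""Training of the scaling parameters (a, a', b, b') by MAD minimization.

Each reaction error is affine in the four parameters,

    err_k = const_k + a * X^SSnd_k + b * X^SS_k + a' * X^OSd_k + b' * X^OS_k,

where e.g. X^OSd_k = K sum_s nu_s r_D(s) E_OS(s) (K the hartree -> kcal/mol
conversion).  Minimizing the mean absolute error is therefore a convex
least-absolute-deviations problem, solved exactly by linear programming
(one slack variable per reaction, HiGHS backend); a derivative-free
Nelder-Mead multistart is available as an independent cross-check.
An RMSD objective reduces to ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import linprog, minimize

from .benchmark import ReactionSet
from .constants import HARTREE_TO_KCAL
from .scaling import ScalingParams

__all__ = ["FitSpec", "FitResult", "fit", "profile", "design_matrix",
           "RankDeficiencyWarning", "PARAM_ORDER"]

PARAM_ORDER = ("a", "ap", "b", "bp")


class RankDeficiencyWarning(UserWarning):
    """The objective is (nearly) independent of some free direction."""


@dataclasses.dataclass
class FitSpec:
    """Which of (a, ap, b, bp) to optimize, values for the rest, objective."""

    free: tuple[str, ...] = PARAM_ORDER
    fixed: dict[str, float] = dataclasses.field(default_factory=dict)
    objective: str = "mad"            # mad | rmsd
    seed: int = 0
    cross_check: bool = False         # Nelder-Mead multistart agreement

    def __post_init__(self):
        bad = [p for p in tuple(self.free) + tuple(self.fixed) if p not in PARAM_ORDER]
        if bad:
            raise ValueError(f"unknown parameters {bad}; use {PARAM_ORDER}")
        if not self.free:
            raise ValueError("at least one parameter must be free")
        if set(self.free) & set(self.fixed):
            raise ValueError("parameters cannot be both free and fixed")
        if self.objective not in ("mad", "rmsd"):
            raise ValueError("objective must be 'mad' or 'rmsd'")

    def full_params(self, theta: np.ndarray, name: str = "fit") -> ScalingParams:
        vals = {p: 0.0 for p in PARAM_ORDER}
        vals.update(self.fixed)
        for p, v in zip(self.free, theta):
            vals[p] = float(v)
        return ScalingParams(vals["a"], vals["ap"], vals["b"], vals["bp"], name)


@dataclasses.dataclass
class FitResult:
    params: ScalingParams
    objective: float                 # kcal/mol
    objective_initial: float
    iterations: int
    converged: bool
    null_directions: list[str] = dataclasses.field(default_factory=list)


def design_matrix(rset: ReactionSet) -> tuple[np.ndarray, np.ndarray]:
    """(M, c): err = c + M @ (a, ap, b, bp) in kcal/mol, one row per reaction."""
    k = HARTREE_TO_KCAL
    rows, consts = [], []
    for rxn in rset.reactions:
        x = np.zeros(4)
        const = -rxn.reference_kcal
        for label, nu in rxn.stoichiometry.items():
            rec = rset.species[label]
            idx = rec.correlation_indices()
            const += nu * rec.e_hf * k
            x[0] += nu * idx.r_nd * rec.e_ss * k     # a
            x[1] += nu * idx.r_d * rec.e_os * k      # ap
            x[2] += nu * rec.e_ss * k                # b
            x[3] += nu * rec.e_os * k                # bp
        rows.append(x)
        consts.append(const)
    return np.array(rows), np.array(consts)


def _objective_value(m, c, theta, kind):
    r = c + m @ theta
    return float(np.mean(np.abs(r))) if kind == "mad" else float(
        np.sqrt(np.mean(r ** 2)))


def fit(rset: ReactionSet, spec: FitSpec = FitSpec()) -> FitResult:
    """Minimize the objective over the free parameters (convex, exact).

    Emits :class:`RankDeficiencyWarning` when the training set leaves a free
    direction undetermined (the direction is reported and also listed in the
    result).  The achieved objective never exceeds the value at the canonical
    MP2 starting point.
    """
    m4, c = design_matrix(rset)
    free_idx = [PARAM_ORDER.index(p) for p in spec.free]
    fixed_theta = np.zeros(4)
    # canonical MP2 default for parameters that are neither free nor fixed
    defaults = {"a": 0.0, "ap": 0.0, "b": 1.0, "bp": 1.0}
    for i, p in enumerate(PARAM_ORDER):
        if p in spec.fixed:
            fixed_theta[i] = spec.fixed[p]
        elif p not in spec.free:
            fixed_theta[i] = defaults[p]
    m = m4[:, free_idx]
    c_eff = c + m4 @ (fixed_theta * (~np.isin(np.arange(4), free_idx)))

    null_dirs = []
    sing = np.linalg.svd(m, compute_uv=False) if m.size else np.array([0.0])
    scale = np.linalg.norm(m) + 1e-300
    if len(m) < len(free_idx) or sing.min() < 1e-10 * scale:
        _, _, vt = np.linalg.svd(m)
        for row in vt[len(sing[sing > 1e-10 * scale]):]:
            null_dirs.append(" + ".join(
                f"{w:+.3f}*{p}" for w, p in zip(row, spec.free) if abs(w) > 1e-8))
        warnings.warn(
            f"training set underdetermines the fit; null direction(s): "
            f"{null_dirs}", RankDeficiencyWarning, stacklevel=2)

    x0 = np.array([defaults[p] for p in spec.free])
    f0 = _objective_value(m, c_eff, x0, spec.objective)

    if spec.objective == "rmsd":
        theta, *_ = np.linalg.lstsq(m, -c_eff, rcond=None)
        iters, ok = 1, True
    else:
        n, k = m.shape
        # variables: theta (free, unbounded) then u >= |err|
        a_ub = np.block([[m, -np.eye(n)], [-m, -np.eye(n)]])
        b_ub = np.concatenate([-c_eff, c_eff])
        cost = np.concatenate([np.zeros(k), np.ones(n) / n])
        res = linprog(cost, A_ub=a_ub, b_ub=b_ub,
                      bounds=[(None, None)] * k + [(0, None)] * n,
                      method="highs")
        if not res.success:
            raise RuntimeError(f"LP solver failed: {res.message}")
        theta = res.x[:k]
        iters, ok = int(res.nit), True

    fval = _objective_value(m, c_eff, theta, spec.objective)
    if spec.cross_check and spec.objective == "mad":
        rng = np.random.default_rng(spec.seed)
        best = fval
        for _ in range(4):
            start = theta + rng.normal(scale=0.5, size=len(theta))
            r = minimize(lambda t: _objective_value(m, c_eff, t, "mad"),
                         start, method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, r.fun)
        if fval - best > 1e-4:
            raise RuntimeError(
                f"LP optimum {fval:.6f} disagrees with multistart {best:.6f}")
    params = spec.full_params(theta)
    return FitResult(params, fval, f0, iters, ok, null_dirs)


def profile(rset: ReactionSet, spec: FitSpec, grid_params: tuple[str, str],
            grids: tuple[np.ndarray, np.ndarray],
            at: ScalingParams | None = None) -> np.ndarray:
    """Objective surface over two parameters, the rest held at ``at``.

    ``grid_params`` must be free parameters of the fit spec (scanning a fixed
    parameter is a configuration error).
    """
    for p in grid_params:
        if p not in spec.free:
            raise ValueError(f"cannot scan fixed parameter {p!r}")
    m4, c = design_matrix(rset)
    base = np.zeros(4)
    if at is not None:
        base[:] = [at.a, at.ap, at.b, at.bp]
    else:
        for p, v in spec.fixed.items():
            base[PARAM_ORDER.index(p)] = v
    i0, i1 = (PARAM_ORDER.index(p) for p in grid_params)
    g0, g1 = grids
    out = np.empty((len(g0), len(g1)))
    for i, v0 in enumerate(g0):
        for j, v1 in enumerate(g1):
            theta = base.copy()
            theta[i0], theta[i1] = v0, v1
            out[i, j] = _objective_value(m4, c, theta, spec.objective)
    return out
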