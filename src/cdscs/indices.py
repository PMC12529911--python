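"""Dynamic/nondynamic correlation indices from natural-orbital occupancies.

For occupancies n_i^s in [0, 1] (per spin channel s) and N electrons:

    I_ND = (1/N)  sum_{i,s} n_i^s (1 - n_i^s)
    I_D  = (1/2N) sum_{i,s} sqrt(n_i^s (1 - n_i^s)) - I_ND
    I_T  = I_ND + I_D

I_D >= 0 always, because sqrt(x)/2 >= x for x in [0, 1/4].  The ratios
r_D = I_D/I_T and r_ND = I_ND/I_T drive the correlation-driven scaling model;
a near-idempotent spectrum (I_T below ``IT_EPS``) is treated as the purely
dynamic limit r_D = 1.  The per-orbital diagnostic I_ND^max is the largest
single-orbital term max n(1-n); species above 0.030 are flagged as suspect
multireference cases.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["OccupancySpectrum", "CorrelationIndices", "index_nd", "index_d",
           "indices", "IT_EPS"]

#: I_T below this is treated as an idempotent (uncorrelated) spectrum.
IT_EPS = 1e-12

_CLAMP = 1e-8


@dataclasses.dataclass
class OccupancySpectrum:
    """Natural-orbital occupancies per spin channel plus the electron count.

    ``n_electrons`` is the normalization N of the indices; by default the
    true electron count (all-electron convention) even if a frozen-core
    amplitude set produced the spectrum.
    """

    alpha: np.ndarray
    beta: np.ndarray
    n_electrons: float

    def __post_init__(self):
        for ch in ("alpha", "beta"):
            v = np.asarray(getattr(self, ch), dtype=float).ravel()
            if v.size and (v.min() < -_CLAMP or v.max() > 1.0 + _CLAMP):
                raise ValueError(
                    f"{ch} occupancy outside [0,1] beyond {_CLAMP:g}: "
                    f"[{v.min()}, {v.max()}]")
            object.__setattr__(self, ch, np.clip(v, 0.0, 1.0))
        if self.n_electrons <= 0:
            raise ValueError("n_electrons must be positive")

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate([self.alpha, self.beta])

    def trace_defect(self) -> float:
        """| sum(occupancies) - N | (zero for particle-conserving sources)."""
        return float(abs(self.all_values.sum() - self.n_electrons))


@dataclasses.dataclass(frozen=True)
class CorrelationIndices:
    i_nd: float
    i_d: float
    i_t: float
    r_d: float
    r_nd: float
    i_nd_max: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _terms(spectrum: OccupancySpectrum) -> np.ndarray:
    n = spectrum.all_values
    return n * (1.0 - n)


def index_nd(spectrum: OccupancySpectrum) -> float:
    """Nondynamic correlation index I_ND."""
    return float(_terms(spectrum).sum() / spectrum.n_electrons)


def index_d(spectrum: OccupancySpectrum) -> float:
    """Dynamic correlation index I_D (nonnegative)."""
    x = _terms(spectrum)
    val = (0.5 * np.sqrt(x).sum() - x.sum()) / spectrum.n_electrons
    # roundoff guard: analytically >= 0
    return float(max(val, 0.0))


def indices(spectrum: OccupancySpectrum) -> CorrelationIndices:
    """Bundle I_ND, I_D, I_T, the ratios and the I_ND^max diagnostic."""
    x = _terms(spectrum)
    i_nd = float(x.sum() / spectrum.n_electrons)
    i_d = float(max((0.5 * np.sqrt(x).sum() - x.sum()) / spectrum.n_electrons, 0.0))
    i_t = i_nd + i_d
    if i_t < IT_EPS:
        r_d, r_nd = 1.0, 0.0
    else:
        r_nd = i_nd / i_t
        r_d = 1.0 - r_nd
    i_nd_max = float(x.max()) if x.size else 0.0
    return CorrelationIndices(i_nd, i_d, i_t, r_d, r_nd, i_nd_max)
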