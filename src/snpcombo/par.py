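"""Population-attributable-risk (PAR) calculators and PAR-RR-frequency algebra.

Four variants are provided:

* Levin's formula  PAR = f(RR-1) / (1 + f(RR-1))  with f the exposure
  prevalence in the population (here: all controls) and RR the crude
  relative risk, approximated by the OR in a case-control design.
* The case-based (Miettinen) form  PAR = p_c (RR-1)/RR  with p_c the
  exposure prevalence among cases — the form that remains valid when RR
  is a confounder-adjusted estimate.
* A multi-level extension summing the case-based form over non-reference
  genotype levels (heterozygous and homozygous vs reference).
* The combined PAR of independent risk factors, 1 - prod(1 - PAR_i).

:func:`rr_given_par` inverts Levin's formula: the relative risk a factor
of frequency f must carry to account for a given PAR.  It quantifies why
frequent low-risk variants can carry a large attributable fraction — at
PAR 30%, a factor present in 10% of the population needs RR 5.3, one
present in 40% only RR 2.1, and the curve never falls below 1.43.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PARResult:
    """An attributable-risk value with the formula variant and inputs that
    produced it."""

    par: float
    variant: str  # levin | case_based | multilevel | combined
    inputs: dict = field(default_factory=dict)

    def as_percent(self) -> int:
        return int(round(100 * self.par))


def par_levin(f: float, rr: float) -> float:
    """Levin PAR from population exposure prevalence and (crude) RR."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence f={f} outside [0, 1]")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    x = f * (rr - 1.0)
    return x / (1.0 + x)


def par_case_based(p_c: float, rr_adj: float) -> float:
    """Miettinen PAR from exposure prevalence among cases and adjusted RR."""
    if not 0.0 <= p_c <= 1.0:
        raise ValueError(f"case prevalence p_c={p_c} outside [0, 1]")
    if rr_adj <= 0:
        raise ValueError(f"relative risk must be positive, got {rr_adj}")
    return p_c * (rr_adj - 1.0) / rr_adj


def par_multilevel(p_c_by_level: Sequence[float], rr_by_level: Sequence[float]) -> float:
    """Case-based PAR summed over non-reference exposure levels."""
    p = np.asarray(p_c_by_level, dtype=float)
    r = np.asarray(rr_by_level, dtype=float)
    if p.shape != r.shape:
        raise ValueError("prevalence and RR vectors must have equal length")
    if (p < 0).any() or p.sum() > 1 + 1e-12:
        raise ValueError("level prevalences must be non-negative and sum to <= 1")
    if (r <= 0).any():
        raise ValueError("relative risks must be positive")
    return float((p * (r - 1.0) / r).sum())


def combined_par(pars: Sequence[float]) -> float:
    """Combined PAR of independent risk factors: 1 - prod(1 - PAR_i)."""
    arr = np.asarray(list(pars), dtype=float)
    if arr.size == 0:
        return 0.0
    if (arr < 0).any() or (arr >= 1).any():
        raise ValueError("each PAR must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - arr))


def rr_given_par(par: float, f: float) -> float:
    """Relative risk required for a factor of frequency f to account for a
    given PAR; the exact inverse of :func:`par_levin`."""
    if not 0.0 <= par < 1.0:
        raise ValueError(f"PAR={par} outside [0, 1)")
    if par == 0.0:
        return 1.0
    if f <= 0.0 or f > 1.0:
        raise ValueError(f"frequency f={f} must lie in (0, 1] for PAR > 0")
    return 1.0 + par / (f * (1.0 - par))


def rr_frequency_curve(par: float, f_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """The RR-vs-frequency curve at fixed PAR (frequency grid default
    0.01..1 step 0.01); its infimum is attained at f = 1."""
    if f_grid is None:
        f_grid = np.arange(0.01, 1.0 + 1e-9, 0.01)
    f = np.asarray(f_grid, dtype=float)
    rr = np.array([rr_given_par(par, fi) for fi in f])
    return pd.DataFrame({"frequency": f, "rr": rr})
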