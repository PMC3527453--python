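"""Bootstrap rank stability and permutation calibration of parametric p-values.

Two Monte-Carlo diagnostics for the combination scan:

* :func:`bootstrap_stability` redraws the stratum (cases and controls
  separately, with replacement, at their original sizes) B times, rescans
  each replicate with identical settings and counts how often the original
  top-10 combinations reappear among the replicate top-10/20/50.  Unstable
  rankings are the signature of noise-driven "optimal" combinations.

* :func:`permutation_calibration` permutes case-control labels P times
  with exposure fixed and compares the permutation null of the Wald
  statistic with its nominal chi-square(1) reference: the permuted mean
  should be approximately 1 and the variance approximately 2 when the
  parametric p-values are trustworthy; sparse high-order conjunctions
  violate this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData
from .indicators import Combination
from .scan import CountsTable, _ScanEngine, wald_stat_p


@dataclass
class StabilityReport:
    """Appearance counts of the original top-10 combinations across
    bootstrap replicate scans."""

    counts: pd.DataFrame  # one row per original top-10 combination
    B: int
    seed: int | None
    order: int
    stratum: str
    n_degenerate: int  # replicate/combination pairs with no defined OR

    def __post_init__(self) -> None:
        for lo, hi in zip(self.counts.columns[1:-1], self.counts.columns[2:]):
            if lo.startswith("top") and hi.startswith("top"):
                assert (self.counts[lo] <= self.counts[hi]).all()


def bootstrap_stability(
    cohort: CohortData,
    k: int,
    stratum: str = "all",
    B: int = 500,
    sizes: Sequence[int] = (10, 20, 50),
    seed=None,
    metric: str = "p",
    identity: bool = False,
) -> StabilityReport:
    """Count reappearances of the original top-10 among bootstrap top lists.

    Cases and controls are resampled separately with replacement at their
    original sizes, preserving the case-control balance of the stratum.
    ``identity=True`` replaces resampling by the identity (every replicate
    is the original sample) — a degenerate mode used to validate the
    counting path.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sizes = tuple(sorted(sizes))
    engine = _ScanEngine(cohort, k, stratum)
    case_idx = np.flatnonzero(engine.status == 1)
    ctrl_idx = np.flatnonzero(engine.status == 0)
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError(f"stratum {stratum!r} too small to resample")
    original = engine.rank(engine.score(), metric)
    top_keys = list(original["key"].head(10))

    rng = np.random.default_rng(seed)
    hits = {key: {s: 0 for s in sizes} for key in top_keys}
    n_degenerate = 0
    for _ in range(B):
        if identity:
            idx = np.concatenate([case_idx, ctrl_idx])
        else:
            idx = np.concatenate([
                rng.choice(case_idx, size=len(case_idx), replace=True),
                rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True),
            ])
        scored = engine.score(idx)
        n_degenerate += int((scored["reason"] != "").sum())
        ranked = engine.rank(scored, metric)
        for s in sizes:
            present = set(ranked["key"].head(s))
            for key in top_keys:
                if key in present:
                    hits[key][s] += 1
    counts = pd.DataFrame(
        [{"key": key, **{f"top{s}": hits[key][s] for s in sizes}} for key in top_keys]
    )
    counts["original_rank"] = np.arange(1, len(top_keys) + 1)
    return StabilityReport(counts=counts, B=B, seed=seed, order=k,
                           stratum=stratum, n_degenerate=n_degenerate)


@dataclass
class CalibrationReport:
    """Permutation null of the Wald statistic, per combination.

    ``mean_stat``/``var_stat`` are the moments of the permuted statistics
    (chi-square(1) reference: 1 and 2); ``p_perm`` uses the add-one
    estimator (r+1)/(P+1).
    """

    table: pd.DataFrame
    P: int
    seed: int | None
    stratum: str


def permutation_calibration(
    cohort: CohortData,
    combinations: Sequence[Combination],
    P: int = 100_000,
    seed=None,
    stratum: str = "all",
) -> CalibrationReport:
    """Permute case-control labels P times with exposure columns fixed.

    For each combination the labels are permuted among the subjects with
    defined exposure; the Wald statistic of each permuted 2x2 table is
    computed exactly as in the observed scan (including the Haldane-
    Anscombe correction).  Permutations in which the combination's table
    has an empty margin contribute no statistic and are tallied as skips.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    mask = cohort.stratum_mask(stratum)
    status_all = cohort.status[mask]
    rng = np.random.default_rng(seed)
    rows = []
    for combo in combinations:
        genotypes = {p: cohort.genotypes(p)[mask] for p in combo.polymorphisms}
        exposed, defined = combo.exposure(genotypes)
        e = exposed[defined]
        status = status_all[defined]
        n = len(status)
        n1 = int(status.sum())
        m1 = int(e.sum())
        counts_obs = CountsTable(
            int((e & (status == 1)).sum()), int((e & (status == 0)).sum()),
            int((~e & (status == 1)).sum()), int((~e & (status == 0)).sum()),
        )
        wald_obs, p_raw = wald_stat_p(counts_obs)

        # permute labels: a = exposed cases per permutation
        perm = np.tile(status.astype(np.int8), (P, 1))
        rng.permuted(perm, axis=1, out=perm)
        a = perm @ e.astype(np.int64)
        b = m1 - a
        c = n1 - a
        d = (n - n1) - b
        cells = np.stack([a, b, c, d], axis=1).astype(float)
        degenerate = (
            (cells[:, 0] + cells[:, 1] == 0) | (cells[:, 2] + cells[:, 3] == 0)
            | (cells[:, 0] + cells[:, 2] == 0) | (cells[:, 1] + cells[:, 3] == 0)
        )
        needs_corr = (cells == 0).any(axis=1)
        cells[needs_corr] += 0.5
        log_or = np.log(cells[:, 0] * cells[:, 3]) - np.log(cells[:, 1] * cells[:, 2])
        var = (1 / cells).sum(axis=1)
        wald = np.where(degenerate, np.nan, log_or**2 / var)
        valid = wald[~np.isnan(wald)]
        r = int((valid >= wald_obs).sum())
        rows.append({
            "key": combo.key,
            "wald_obs": wald_obs,
            "p_raw": p_raw,
            "p_perm": (r + 1) / (len(valid) + 1),
            "mean_stat": float(valid.mean()),
            "var_stat": float(valid.var(ddof=0)),
            "n_skipped": int(np.isnan(wald).sum()),
            "exposed": m1,
            "n": n,
        })
    return CalibrationReport(table=pd.DataFrame(rows), P=P, seed=seed, stratum=stratum)


def chi2_reference_moments() -> tuple[float, float]:
    """Mean and variance of the chi-square(1) reference distribution."""
    return float(stats.chi2.mean(1)), float(stats.chi2.var(1))
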