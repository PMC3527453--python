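"""Exhaustive k-way combination scans with 2x2 odds-ratio scoring.

Every candidate combination of ``order`` risk indicators is scored in a
smoking stratum with the crude odds ratio OR = ad/(bc) of its conjunction
exposure against case status, a Woolf (log-scale) 95% confidence
interval, the Wald statistic (ln OR / SE)^2 referred to chi-square(1),
and a Bonferroni-adjusted p-value whose denominator is the number of
enumerated candidates of that order in that stratum.

The model/results split follows the statsmodels convention:
``CombinationScan(cohort, order=2, stratum="non").fit()`` returns a
:class:`ScanResults` holding the ranked table, with ``summary()``,
``top()`` and resampling diagnostics attached.

Zero cells are handled with the Haldane-Anscombe correction (+0.5 to all
four cells); tables with an entirely empty margin (e.g. no exposed
subject in either group) have no defined OR and are excluded from the
ranking but logged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData
from .indicators import Combination, count_combinations, enumerate_combinations

LOW_COUNT_THRESHOLD = 100  # flag sparse-exposure results, cf. dashed-line caveat


class DegenerateTableError(ValueError):
    """The 2x2 table has an empty margin; the odds ratio is undefined."""


class CountsTable(NamedTuple):
    """Cells of the exposure-by-status table: a/b exposed cases/controls,
    c/d unexposed cases/controls."""

    a: int
    b: int
    c: int
    d: int


def _corrected(counts: CountsTable) -> tuple[float, float, float, float]:
    a, b, c, d = counts
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise DegenerateTableError(f"empty margin in table {tuple(counts)}")
    if min(a, b, c, d) == 0:  # Haldane-Anscombe
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def odds_ratio_ci(
    counts: CountsTable, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Crude odds ratio with Woolf confidence interval.

    OR = ad/(bc); CI = exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a+1/b+1/c+1/d)).
    """
    a, b, c, d = _corrected(counts)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log(or_)
    return float(or_), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def wald_stat_p(counts: CountsTable) -> tuple[float, float]:
    """Wald statistic (ln OR / SE)^2 and its chi-square(1) upper-tail p."""
    a, b, c, d = _corrected(counts)
    log_or = np.log((a * d) / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    wald = float(log_or**2 / var)
    return wald, float(stats.chi2.sf(wald, df=1))


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError(f"p_raw={p_raw} outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def two_by_two(
    cohort: CohortData, combination: Combination, stratum: str = "all"
) -> CountsTable:
    """Tally conjunction exposure against status among subjects with
    defined exposure in the stratum (complete-case per combination)."""
    mask = cohort.stratum_mask(stratum)
    if not mask.any():
        raise ValueError(f"stratum {stratum!r} is empty after exclusions")
    genotypes = {p: cohort.genotypes(p)[mask] for p in combination.polymorphisms}
    exposed, defined = combination.exposure(genotypes)
    status = cohort.status[mask]
    case = (status == 1) & defined
    ctrl = (status == 0) & defined
    return CountsTable(
        a=int(np.count_nonzero(exposed & case)),
        b=int(np.count_nonzero(exposed & ctrl)),
        c=int(np.count_nonzero(~exposed & case)),
        d=int(np.count_nonzero(~exposed & ctrl)),
    )


# ---------------------------------------------------------------------------
# scan engine (shared with the bootstrap)


class _ScanEngine:
    """Precomputed indicator exposure matrices for fast repeated scans.

    Rows of ``expo`` are per-indicator exposure booleans, rows of
    ``defined`` are per-polymorphism non-missing booleans, over the
    subjects of one stratum.  Bootstrap replicates rescore by column
    (subject) indexing without touching the cohort again.
    """

    def __init__(self, cohort: CohortData, order: int, stratum: str = "all"):
        mask = cohort.stratum_mask(stratum)
        if not mask.any():
            raise ValueError(f"stratum {stratum!r} is empty after exclusions")
        self.status = cohort.status[mask]
        self.order = order
        self.stratum = stratum
        domains = {p: cohort.domains[p] for p in cohort.polymorphisms}
        self.combos = list(enumerate_combinations(domains, order))
        self.m = len(self.combos)
        assert self.m == count_combinations(
            sum(1 for d in domains.values() if len(d) == 3),
            sum(1 for d in domains.values() if len(d) == 2),
            order,
        )
        # index indicators once
        ind_index: dict = {}
        for combo in self.combos:
            for ind in combo.indicators:
                ind_index.setdefault(ind, len(ind_index))
        poly_index = {p: i for i, p in enumerate(cohort.polymorphisms)}
        n = int(mask.sum())
        self.expo = np.empty((len(ind_index), n), dtype=bool)
        self.defined = np.empty((len(poly_index), n), dtype=bool)
        geno = {p: cohort.genotypes(p)[mask] for p in cohort.polymorphisms}
        for p, i in poly_index.items():
            self.defined[i] = geno[p] != -1
        for ind, i in ind_index.items():
            self.expo[i] = ind.is_exposed(geno[ind.polymorphism])
        self._rows = [
            (
                combo,
                np.array([ind_index[i] for i in combo.indicators]),
                np.array([poly_index[p] for p in combo.polymorphisms]),
            )
            for combo in self.combos
        ]

    def score(self, subject_idx: np.ndarray | None = None) -> pd.DataFrame:
        """Score every candidate; ``subject_idx`` (with repeats) selects a
        bootstrap replicate.  Returns one row per candidate with cells,
        OR/CI, Wald statistic and raw p; degenerate tables get NaN scores
        and a reason."""
        if subject_idx is None:
            expo, defined, status = self.expo, self.defined, self.status
        else:
            expo = self.expo[:, subject_idx]
            defined = self.defined[:, subject_idx]
            status = self.status[subject_idx]
        case = status == 1
        rows = []
        for combo, ind_idx, poly_idx in self._rows:
            e = np.logical_and.reduce(expo[ind_idx])
            d = np.logical_and.reduce(defined[poly_idx])
            ed = e & d
            n_def = int(d.sum())
            a = int(np.count_nonzero(ed & case))
            m1 = int(ed.sum())
            n1 = int(np.count_nonzero(d & case))
            counts = CountsTable(a, m1 - a, n1 - a, n_def - m1 - (n1 - a))
            row = {"key": combo.key, "a": counts.a, "b": counts.b,
                   "c": counts.c, "d": counts.d}
            try:
                or_, lo, hi = odds_ratio_ci(counts)
                wald, p_raw = wald_stat_p(counts)
                row.update(odds_ratio=or_, ci_lo=lo, ci_hi=hi,
                           wald=wald, p_raw=p_raw, reason="")
            except DegenerateTableError:
                row.update(odds_ratio=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                           wald=np.nan, p_raw=np.nan, reason="empty margin")
            rows.append(row)
        return pd.DataFrame(rows)

    def rank(self, scored: pd.DataFrame, metric: str) -> pd.DataFrame:
        """Deterministic ranking of scorable candidates.

        ``metric="p"`` ranks by ascending raw p (equivalently adjusted p,
        the denominator being shared), ``metric="or"`` by descending OR.
        Ties break by larger \\|ln OR\\|, then lexicographic key.
        """
        ok = scored[scored["reason"] == ""].copy()
        if ok.empty:
            raise ValueError("no scorable candidate (all tables degenerate)")
        ok["abs_log_or"] = np.abs(np.log(ok["odds_ratio"]))
        if metric in ("p", "min_p_adj"):
            ok = ok.sort_values(["p_raw", "abs_log_or", "key"],
                                ascending=[True, False, True], kind="mergesort")
        elif metric in ("or", "max_or"):
            ok = ok.sort_values(["odds_ratio", "p_raw", "key"],
                                ascending=[False, True, True], kind="mergesort")
        else:
            raise ValueError(f"unknown ranking metric {metric!r}")
        ok = ok.drop(columns="abs_log_or").reset_index(drop=True)
        ok.insert(0, "rank", np.arange(1, len(ok) + 1))
        return ok


# ---------------------------------------------------------------------------
# model / results


class CombinationScan:
    """Exhaustive scan model over all k-way combinations in one stratum.

    Parameters
    ----------
    cohort
        The case-control cohort.
    order
        Combination size k (1..7 with the default polymorphism panel).
    stratum
        Smoking selector: ``all``/``total``, ``non``, ``former``,
        ``current`` or ``ever``.
    metric
        ``"p"`` (rank by p-value, the tables' ordering) or ``"or"``
        (rank by odds ratio, the optimal-OR profile variant).
    """

    def __init__(self, cohort: CohortData, order: int, stratum: str = "all",
                 metric: str = "p"):
        if order < 1 or order > len(cohort.polymorphisms):
            raise ValueError(f"order={order} outside 1..{len(cohort.polymorphisms)}")
        self.cohort = cohort
        self.order = order
        self.stratum = stratum
        self.metric = metric
        self._engine = _ScanEngine(cohort, order, stratum)

    def fit(self) -> "ScanResults":
        engine = self._engine
        scored = engine.score()
        ranked = engine.rank(scored, self.metric)
        ranked["p_adj"] = np.minimum(1.0, engine.m * ranked["p_raw"])
        ranked["m"] = engine.m
        ranked["flagged"] = (ranked["a"] < LOW_COUNT_THRESHOLD) | (
            ranked["b"] < LOW_COUNT_THRESHOLD
        )
        by_key = {c.key: c for c in engine.combos}
        ranked["label"] = [by_key[k].label(self.cohort.allele_maps)
                           for k in ranked["key"]]
        excluded = scored.loc[scored["reason"] != "", ["key", "reason"]].reset_index(
            drop=True
        )
        return ScanResults(self, ranked, excluded, by_key)


@dataclass
class ScanResults:
    """Ranked association results of one combination scan."""

    model: CombinationScan
    table: pd.DataFrame
    excluded: pd.DataFrame
    _combinations: Mapping[str, Combination]

    @property
    def m(self) -> int:
        """Bonferroni denominator: enumerated candidates of this order."""
        return int(self.table["m"].iloc[0])

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def combination(self, key: str) -> Combination:
        return self._combinations[key]

    @property
    def top_combinations(self) -> list[Combination]:
        return [self._combinations[k] for k in self.top(10)["key"]]

    def summary(self, n: int = 10) -> str:
        eng = self.model._engine
        n_ca = int((eng.status == 1).sum())
        n_co = int((eng.status == 0).sum())
        head = (
            f"{self.model.order}-way combination scan | stratum={self.model.stratum} "
            f"({n_ca} cases / {n_co} controls)\n"
            f"candidates={self.m}  scored={len(self.table)}  "
            f"excluded={len(self.excluded)}  metric={self.model.metric}\n"
        )
        cols = ["rank", "label", "a", "b", "odds_ratio", "ci_lo", "ci_hi", "p_adj"]
        body = self.top(n)[cols].to_string(
            index=False,
            formatters={
                "odds_ratio": "{:.2f}".format,
                "ci_lo": "{:.2f}".format,
                "ci_hi": "{:.2f}".format,
                "p_adj": "{:.3g}".format,
            },
        )
        return head + body

    # resampling diagnostics (implemented in snpcombo.resampling)
    def bootstrap_stability(self, B: int = 500, sizes: Sequence[int] = (10, 20, 50),
                            seed=None, identity: bool = False):
        from .resampling import bootstrap_stability

        return bootstrap_stability(self.model.cohort, self.model.order,
                                   self.model.stratum, B=B, sizes=sizes, seed=seed,
                                   metric=self.model.metric, identity=identity)

    def permutation_calibration(self, combinations: Iterable[Combination] | None = None,
                                P: int = 10_000, seed=None):
        from .resampling import permutation_calibration

        if combinations is None:
            combinations = self.top_combinations
        return permutation_calibration(self.model.cohort, list(combinations),
                                       P=P, seed=seed, stratum=self.model.stratum)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def scan(cohort: CohortData, k: int, stratum: str = "all", metric: str = "p",
         top_n: int | None = None) -> ScanResults:
    """Functional wrapper: fit a :class:`CombinationScan` and return results
    (optionally truncated to the ``top_n`` best)."""
    res = CombinationScan(cohort, k, stratum, metric).fit()
    if top_n is not None:
        res.table = res.table.head(top_n).copy()
    return res


def optimal_or_profile(cohort: CohortData, orders: Sequence[int] = range(1, 8),
                       strata: Sequence[str] = ("total", "ever", "current",
                                                "former", "non"),
                       metric: str = "p") -> pd.DataFrame:
    """Best combination per (order, stratum): the optimal-OR profile.

    Returns a tidy frame with the winning combination's OR, CI and the
    low-count flag that marks profiles to interpret with caution.
    """
    rows = []
    for stratum in strata:
        for k in orders:
            best = CombinationScan(cohort, k, stratum, metric).fit().top(1).iloc[0]
            rows.append({"stratum": stratum, "order": k, "key": best["key"],
                         "odds_ratio": best["odds_ratio"], "ci_lo": best["ci_lo"],
                         "ci_hi": best["ci_hi"], "p_adj": best["p_adj"],
                         "flagged": bool(best["flagged"])})
    return pd.DataFrame(rows)
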