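"""Covariate-adjusted odds ratios and smoking-stratum heterogeneity tests.

Logistic regression supplies two things the crude 2x2 machinery cannot:
odds ratios adjusted for age, gender, smoking habits and study site, and
a formal test of whether a combination's OR differs between smoking
strata via the exposure-by-stratum interaction coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import CohortData
from .indicators import Combination

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "gender", "smoking", "site")


@dataclass
class LogisticFit:
    """A fitted binary logistic model (ML via Newton's method).

    ``converged`` is False on non-convergence or detected separation; the
    estimates are then diagnostics, not results.
    """

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    separation: bool
    n_used: int
    llf: float

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def or_ci(self, term: str, alpha: float = 0.05) -> tuple[float, float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        beta = self.params[term]
        se = self.se()[term]
        return (float(np.exp(beta)),
                float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))

    def wald_p(self, term: str) -> float:
        z = self.params[term] / self.se()[term]
        return float(2 * stats.norm.sf(abs(z)))


def fit_logistic(response: np.ndarray, design: pd.DataFrame,
                 add_const: bool = True, maxiter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Fit a logistic regression; separation and non-convergence are
    flagged, never silently returned as converged estimates."""
    X = pd.DataFrame(design).astype(float)
    if add_const:
        X = sm.add_constant(X, has_constant="add")
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response and design length mismatch")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns)")
    model = sm.Logit(y, X)
    separation = False
    converged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            res = model.fit(method="bfgs", maxiter=maxiter, disp=False)
            converged = False
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        separation, converged = True, False
    # huge coefficients with fitted probabilities pinned at 0/1 mean separation too
    if converged and np.abs(res.params).max() > 15:
        fitted = res.predict()
        if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8) | ~np.isfinite(fitted)):
            separation, converged = True, False
    with np.errstate(all="ignore"):
        cov = res.cov_params()
    return LogisticFit(params=res.params, cov=pd.DataFrame(cov),
                       converged=converged and not separation,
                       separation=separation, n_used=len(y), llf=float(res.llf))


def _categorical_dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Reference-coded dummies with the first observed level as reference."""
    levels = list(pd.unique(series))
    cols = {}
    for lev in levels[1:]:
        cols[f"{prefix}[{lev}]"] = (series == lev).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _analysis_frame(cohort: CohortData, combination: Combination,
                    covariates: Sequence[str], mask: np.ndarray) -> pd.DataFrame:
    genotypes = {p: cohort.genotypes(p)[mask] for p in combination.polymorphisms}
    exposed, defined = combination.exposure(genotypes)
    df = cohort.table.loc[mask, ["status", *covariates]].reset_index(drop=True)
    df["exposure"] = exposed.astype(float)
    df = df[defined]
    if "smoking" in covariates:
        df = df[df["smoking"] != "unknown"]
    return df.dropna().reset_index(drop=True)


def adjusted_or(cohort: CohortData, exposure: Combination,
                covariates: Sequence[str] = DEFAULT_COVARIATES,
                stratum: str = "all") -> tuple[float, tuple[float, float], LogisticFit]:
    """Covariate-adjusted OR of a combination: the exponentiated exposure
    coefficient of ``status ~ exposure + covariates`` with a Wald CI.

    With ``covariates=()`` this reduces to the crude 2x2 OR exactly.
    """
    mask = cohort.stratum_mask(stratum)
    df = _analysis_frame(cohort, exposure, covariates, mask)
    if df["exposure"].nunique() < 2:
        raise ValueError("exposure is constant in the analysis subset (rank deficiency)")
    design = pd.DataFrame({"exposure": df["exposure"]})
    for cov in covariates:
        if cov == "age":
            design["age"] = df["age"].astype(float)
        else:
            design = pd.concat([design, _categorical_dummies(df[cov], cov)], axis=1)
    fit = fit_logistic(df["status"].to_numpy(), design)
    or_, lo, hi = fit.or_ci("exposure")
    return or_, (lo, hi), fit


@dataclass
class HeterogeneityResult:
    """Exposure-by-stratum interaction test of OR heterogeneity."""

    beta_int: float
    p_int: float
    or_by_stratum: Mapping[str, float]
    strata: tuple[str, str]
    fit: LogisticFit

    def summary(self) -> str:
        s0, s1 = self.strata
        return (
            f"OR heterogeneity across smoking strata ({s0} vs {s1})\n"
            f"  OR[{s0}] = {self.or_by_stratum[s0]:.3f}   "
            f"OR[{s1}] = {self.or_by_stratum[s1]:.3f}\n"
            f"  interaction beta = {self.beta_int:.4f} "
            f"(ratio of ORs = {np.exp(self.beta_int):.3f}), "
            f"Wald p = {self.p_int:.3g}"
        )


def interaction_test(cohort: CohortData, combination: Combination,
                     strata: tuple[str, str] = ("non", "ever"),
                     covariates: Sequence[str] = ()) -> HeterogeneityResult:
    """Test whether a combination's OR differs between two smoking strata.

    Fits ``status ~ exposure + stratum + exposure:stratum`` on the union
    of the two strata and reads the Wald p-value of the interaction
    coefficient.  In this covariate-free (saturated) model
    ``exp(beta_int)`` equals the ratio of the two stratum ORs exactly.
    """
    s0, s1 = strata
    mask0 = cohort.stratum_mask(s0)
    mask1 = cohort.stratum_mask(s1)
    if (mask0 & mask1).any():
        raise ValueError(f"strata {strata} overlap")
    if not mask0.any() or not mask1.any():
        raise ValueError("both strata must be non-empty")
    mask = mask0 | mask1
    genotypes = {p: cohort.genotypes(p)[mask] for p in combination.polymorphisms}
    exposed, defined = combination.exposure(genotypes)
    df = cohort.table.loc[mask, ["status", *covariates]].reset_index(drop=True)
    df["exposure"] = exposed.astype(float)
    df["group"] = np.where(mask1[mask], 1.0, 0.0)
    df = df[defined].dropna().reset_index(drop=True)
    for g in (0.0, 1.0):
        if df.loc[df["group"] == g, "exposure"].nunique() < 2:
            raise ValueError(f"exposure does not vary within stratum {strata[int(g)]!r}")
    design = pd.DataFrame({
        "exposure": df["exposure"],
        "group": df["group"],
        "exposure_x_group": df["exposure"] * df["group"],
    })
    for cov in covariates:
        if cov == "age":
            design["age"] = df["age"].astype(float)
        else:
            design = pd.concat([design, _categorical_dummies(df[cov], cov)], axis=1)
    fit = fit_logistic(df["status"].to_numpy(), design)
    ors = {}
    for name, g in ((s0, 0.0), (s1, 1.0)):
        sub = df[df["group"] == g]
        a = ((sub["exposure"] == 1) & (sub["status"] == 1)).sum()
        b = ((sub["exposure"] == 1) & (sub["status"] == 0)).sum()
        c = ((sub["exposure"] == 0) & (sub["status"] == 1)).sum()
        d = ((sub["exposure"] == 0) & (sub["status"] == 0)).sum()
        ors[name] = float((a * d) / (b * c)) if b * c > 0 else float("nan")
    return HeterogeneityResult(
        beta_int=float(fit.params["exposure_x_group"]),
        p_int=fit.wald_p("exposure_x_group"),
        or_by_stratum=ors,
        strata=strata,
        fit=fit,
    )
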