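"""Synthetic case-control cohort generator with planted conjunction effects.

The generator emulates the statistical structure the scan assumes, so the
whole pipeline is testable without subject-level study data:

* population genotypes at each biallelic SNP drawn under Hardy-Weinberg
  equilibrium at a configurable allele frequency, and a binary deletion
  polymorphism with a configurable null-genotype frequency;
* a configurable distribution of smoking strata with per-stratum
  case/control quotas (retrospective ascertainment: candidates are drawn
  from the population model and kept until both quotas fill);
* planted effects: disease status is sampled from a logistic model in the
  planted conjunction exposures, so each planted (combination, stratum)
  pair carries an exact *conditional* odds ratio;
* covariates: age (normal, status-specific mean), gender and study site
  (categorical), with an optional site confounder that shifts both the
  allele frequencies and the baseline disease odds at one site.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import DELETION_COLUMN, SNP_COLUMNS, CohortData, cohort_from_dataframe
from .indicators import BINARY_DOMAIN, Combination, MISSING, RiskIndicator

_MAX_DRAW_ROUNDS = 200


@dataclass(frozen=True)
class PlantedEffect:
    """A conjunction carrying a conditional odds ratio within a stratum
    ('all' applies in every stratum; 'ever' covers former and current)."""

    combination: Combination
    stratum: str
    odds_ratio: float

    def applies(self, stratum: str) -> bool:
        if self.stratum == "all":
            return True
        if self.stratum == "ever":
            return stratum in ("former", "current")
        return stratum == self.stratum


@dataclass
class SiteConfounder:
    """Makes the last study site both genotype-shifted and higher-risk,
    confounding crude combination ORs."""

    allele_shift: float = 0.15
    logit_shift: float = 1.0


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    ``stratum_sizes`` maps smoking stratum (non/former/current/unknown) to
    (n_cases, n_controls).  ``allele_freq`` gives the frequency of the
    counted allele per SNP; ``deletion_null_freq`` the frequency of the
    homozygous-deletion (null) genotype.
    """

    stratum_sizes: Mapping[str, tuple[int, int]]
    allele_freq: Mapping[str, float] = field(
        default_factory=lambda: {
            "rs1014971": 0.63,
            "rs11892031": 0.08,
            "rs1495741": 0.22,
            "rs710521": 0.74,
            "rs8102137": 0.33,
            "rs9642880": 0.46,
        }
    )
    deletion_null_freq: float = 0.5
    planted: Sequence[PlantedEffect] = ()
    baseline_logit: float = -1.0
    age_mean_control: float = 64.0
    age_mean_case: float = 67.0
    age_sd: float = 10.0
    p_male: float = 0.75
    sites: Sequence[str] = ("site_A", "site_B")
    site_probs: Sequence[float] | None = None
    confounder: SiteConfounder | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for snp, f in self.allele_freq.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"allele frequency for {snp} must lie in (0,1), got {f}")
        if not 0.0 < self.deletion_null_freq < 1.0:
            raise ValueError("deletion null frequency must lie in (0,1)")
        for stratum, (nca, nco) in self.stratum_sizes.items():
            if stratum not in ("non", "former", "current", "unknown"):
                raise ValueError(f"unknown stratum {stratum!r}")
            if nca < 1 or nco < 1:
                raise ValueError(f"stratum sizes must be >= 1, got {stratum}: {(nca, nco)}")
        for eff in self.planted:
            if eff.odds_ratio <= 0:
                raise ValueError("planted odds ratios must be positive")
            if eff.stratum not in ("all", "ever", "non", "former", "current"):
                raise ValueError(f"unknown planted stratum {eff.stratum!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must lie in [0, 1)")


def _draw_genotypes(config: SimulationConfig, m: int, site_codes: np.ndarray,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    shift = 0.0
    if config.confounder is not None:
        shift = config.confounder.allele_shift
    confounded = site_codes == len(config.sites) - 1
    geno: dict[str, np.ndarray] = {}
    for snp in SNP_COLUMNS:
        f = np.full(m, config.allele_freq[snp])
        if shift:
            f = np.clip(f + shift * confounded, 0.01, 0.99)
        geno[snp] = rng.binomial(2, f).astype(np.int8)
    f_null = np.full(m, config.deletion_null_freq)
    if shift:
        f_null = np.clip(f_null + shift * confounded, 0.01, 0.99)
    geno[DELETION_COLUMN] = rng.binomial(1, f_null).astype(np.int8)
    return geno


def simulate_cohort(config: SimulationConfig, seed=None) -> CohortData:
    """Draw a case-control cohort matching the configured stratum quotas.

    Candidates are generated from the population model; disease status is
    Bernoulli with logit = baseline + site shift + sum of ln(OR) over the
    planted exposures active in the candidate's stratum.  Cases and
    controls are retained until each stratum's quotas are filled, mirroring
    retrospective ascertainment, so each planted conditional OR is exact in
    the sampled population model.
    """
    rng = np.random.default_rng(seed)
    site_probs = config.site_probs
    if site_probs is None:
        site_probs = [1.0 / len(config.sites)] * len(config.sites)
    frames = []
    for stratum in ("non", "former", "current", "unknown"):
        if stratum not in config.stratum_sizes:
            continue
        n_ca, n_co = config.stratum_sizes[stratum]
        effects = [e for e in config.planted if e.applies(stratum)]
        got_ca: list[pd.DataFrame] = []
        got_co: list[pd.DataFrame] = []
        need_ca, need_co = n_ca, n_co
        for _ in range(_MAX_DRAW_ROUNDS):
            if need_ca <= 0 and need_co <= 0:
                break
            m = max(2000, 4 * (max(need_ca, 0) + max(need_co, 0)))
            site_codes = rng.choice(len(config.sites), size=m, p=site_probs)
            geno = _draw_genotypes(config, m, site_codes, rng)
            eta = np.full(m, config.baseline_logit)
            if config.confounder is not None:
                eta += config.confounder.logit_shift * (
                    site_codes == len(config.sites) - 1
                )
            for eff in effects:
                exposed, _ = eff.combination.exposure(geno)
                eta += np.log(eff.odds_ratio) * exposed
            status = rng.random(m) < 1.0 / (1.0 + np.exp(-eta))
            batch = pd.DataFrame(geno)
            batch["site"] = np.asarray(config.sites)[site_codes]
            batch["status"] = status.astype(np.int8)
            ca = batch[batch["status"] == 1]
            co = batch[batch["status"] == 0]
            if need_ca > 0:
                got_ca.append(ca.head(need_ca))
                need_ca -= len(got_ca[-1])
            if need_co > 0:
                got_co.append(co.head(need_co))
                need_co -= len(got_co[-1])
        if need_ca > 0 or need_co > 0:
            raise RuntimeError(
                f"could not fill quotas for stratum {stratum!r}; "
                "the configured baseline/effects make one status vanishingly rare"
            )
        sub = pd.concat(got_ca + got_co, ignore_index=True)
        sub["smoking"] = stratum
        frames.append(sub)
    df = pd.concat(frames, ignore_index=True)
    n = len(df)
    status = df["status"].to_numpy()
    age_mean = np.where(status == 1, config.age_mean_case, config.age_mean_control)
    df["age"] = np.round(rng.normal(age_mean, config.age_sd), 1)
    df["gender"] = np.where(rng.random(n) < config.p_male, "male", "female")
    df["id"] = [f"S{i:06d}" for i in range(n)]
    if config.missing_rate > 0:
        for p in SNP_COLUMNS + (DELETION_COLUMN,):
            drop = rng.random(n) < config.missing_rate
            df.loc[drop, p] = MISSING
    cols = ["id", "status", "smoking", "age", "gender", "site",
            *SNP_COLUMNS, DELETION_COLUMN]
    table = df[cols].copy()
    for p in SNP_COLUMNS + (DELETION_COLUMN,):
        table[p] = table[p].astype(np.int8)
    table["status"] = table["status"].astype(np.int8)
    return CohortData(table)


def simulate_smoker_contrast(config: SimulationConfig, seed=None) -> CohortData:
    """Cohort with stratum-heterogeneous planted effects.

    Requires at least two configured smoking strata whose planted odds
    ratios differ for some combination, so the exposure-by-stratum
    interaction test has a well-defined target.
    """
    strata = [s for s in config.stratum_sizes if s != "unknown"]
    if len(strata) < 2:
        raise ValueError("smoker-contrast simulation needs at least two smoking strata")
    per_combo: dict[str, set[float]] = {}
    for eff in config.planted:
        per_combo.setdefault(eff.combination.key, set()).add(eff.odds_ratio)
    if not any(len(v) > 1 for v in per_combo.values()):
        raise ValueError(
            "no combination with stratum-specific odds ratios is planted; "
            "use simulate_cohort for homogeneous effects"
        )
    return simulate_cohort(config, seed=seed)


# ---------------------------------------------------------------------------
# scenarios


def table9_config(**overrides) -> SimulationConfig:
    """Default scenario mirroring the study's marginal smoking structure:
    321/752 non-smoking, 742/656 former-smoking and 431/315 current-smoking
    cases/controls (plus 101/37 with unknown smoking habits), so the
    smoking OR and PAR machinery can be exercised on regenerated data."""
    params = dict(
        stratum_sizes={
            "non": (321, 752),
            "former": (742, 656),
            "current": (431, 315),
            "unknown": (101, 37),
        },
    )
    params.update(overrides)
    return SimulationConfig(**params)


def _combination_from_spec(spec: str) -> Combination:
    """Parse 'rs9642880:12,rs1014971:0,GSTM1:null' into a Combination."""
    inds = []
    for part in spec.split(","):
        poly, _, codes = part.strip().partition(":")
        if not codes:
            raise ValueError(f"bad combination term {part!r}; expected poly:codes")
        if poly == DELETION_COLUMN:
            tokens = {"null": 1, "present": 0, "0": 0, "1": 1}
            rs = tuple(sorted({tokens[t] for t in codes.split("+")}))
            inds.append(RiskIndicator(poly, rs, BINARY_DOMAIN))
        else:
            rs = tuple(sorted(int(ch) for ch in codes.replace("+", "")))
            inds.append(RiskIndicator(poly, rs))
    return Combination(tuple(inds))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a scenario file (see examples/table9.yaml for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    planted = tuple(
        PlantedEffect(
            combination=_combination_from_spec(item["combination"]),
            stratum=item.get("stratum", "all"),
            odds_ratio=float(item["odds_ratio"]),
        )
        for item in raw.pop("planted", [])
    )
    sizes = {k: (int(v[0]), int(v[1])) for k, v in raw.pop("strata").items()}
    conf = raw.pop("confounder", None)
    confounder = SiteConfounder(**conf) if conf else None
    return SimulationConfig(stratum_sizes=sizes, planted=planted,
                            confounder=confounder, **raw)
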