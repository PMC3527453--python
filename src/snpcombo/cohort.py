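"""Subject-level case-control cohort container, TSV I/O and HWE checks.

The cohort is a pandas DataFrame with one row per subject: case/control
status, genotypes at six biallelic bladder-cancer susceptibility SNPs
(variant-allele count 0/1/2), a present/null code for the GSTM1 deletion,
smoking status (non / former / current / unknown) and the covariates age,
gender and study site.  Genotypes may be supplied as 0/1/2 counts or as
allele strings such as ``G/T``; in the latter case the counted allele is
the minor allele estimated from the controls.

Subjects with unknown smoking status are retained in "total"-group
analyses but excluded from any smoking-defined stratum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import BIALLELIC_DOMAIN, BINARY_DOMAIN, MISSING

SNP_COLUMNS: tuple[str, ...] = (
    "rs1014971",
    "rs11892031",
    "rs1495741",
    "rs710521",
    "rs8102137",
    "rs9642880",
)
DELETION_COLUMN = "GSTM1"
POLYMORPHISMS: tuple[str, ...] = SNP_COLUMNS + (DELETION_COLUMN,)

REQUIRED_COLUMNS: tuple[str, ...] = ("id", "status", "smoking", "age", "gender", "site")
SMOKING_LEVELS: tuple[str, ...] = ("non", "former", "current", "unknown")
STRATA: tuple[str, ...] = ("all", "total", "non", "former", "current", "ever")

MISSING_TOKEN = "NA"
_DELETION_TOKENS = {"present": 0, "null": 1, "0": 0, "1": 1}
_DELETION_LABELS = {0: "present", 1: "null"}


class CohortFormatError(ValueError):
    """The input table violates the declared format (e.g. missing columns)."""


class CohortValidationError(ValueError):
    """Rows carry genotype or category codes outside the declared domain."""


@dataclass
class CohortData:
    """Validated case-control cohort.

    Attributes
    ----------
    table
        One row per subject; genotype columns are int8 with -1 for missing.
    polymorphisms
        Genotyped polymorphism columns (order fixes enumeration order).
    domains
        Genotype domain per polymorphism.
    allele_maps
        Optional per-SNP map from genotype code to display string
        (``{0: "G/G", 1: "G/T", 2: "T/T"}``); populated when loading the
        allele-string dialect.
    validation
        JSON-able report of the load: row counts, rejections, stratum tallies.
    """

    table: pd.DataFrame
    polymorphisms: tuple[str, ...] = POLYMORPHISMS
    domains: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    allele_maps: Mapping[str, Mapping[int, str]] | None = None
    validation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domains:
            self.domains = {
                p: BINARY_DOMAIN if p == DELETION_COLUMN else BIALLELIC_DOMAIN
                for p in self.polymorphisms
            }
        missing = [c for c in REQUIRED_COLUMNS + tuple(self.polymorphisms)
                   if c not in self.table.columns]
        if missing:
            raise CohortFormatError(f"missing mandatory columns: {missing}")
        if self.table["status"].isna().any():
            raise CohortValidationError("every subject must have a status")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def n_cases(self) -> int:
        return int((self.table["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.table["status"] == 0).sum())

    @property
    def status(self) -> np.ndarray:
        return self.table["status"].to_numpy(dtype=np.int8)

    def genotypes(self, polymorphism: str) -> np.ndarray:
        return self.table[polymorphism].to_numpy(dtype=np.int8)

    def genotype_map(self) -> dict[str, np.ndarray]:
        return {p: self.genotypes(p) for p in self.polymorphisms}

    # -- strata ------------------------------------------------------------
    def stratum_mask(self, stratum: str = "all") -> np.ndarray:
        """Boolean subject mask for a smoking stratum selector.

        ``all``/``total`` keep every subject (including unknown smoking);
        ``ever`` pools former and current smokers; ``non``, ``former`` and
        ``current`` select a single stratum.  Unknown-smoking subjects are
        excluded from every smoking-defined stratum.
        """
        smoking = self.table["smoking"].to_numpy()
        if stratum in ("all", "total"):
            return np.ones(len(smoking), dtype=bool)
        if stratum == "ever":
            return (smoking == "former") | (smoking == "current")
        if stratum in ("non", "former", "current"):
            return smoking == stratum
        raise ValueError(f"unknown stratum selector {stratum!r}; expected one of {STRATA}")

    def subset(self, mask: np.ndarray) -> "CohortData":
        return CohortData(
            self.table.loc[np.asarray(mask)].reset_index(drop=True),
            self.polymorphisms,
            dict(self.domains),
            self.allele_maps,
        )

    def stratum_counts(self) -> pd.DataFrame:
        """Cases/controls per smoking stratum (rows: non, former, current,
        ever, unknown, total)."""
        rows = {}
        smoking = self.table["smoking"]
        status = self.table["status"]
        for level in ("non", "former", "current", "unknown"):
            sel = smoking == level
            rows[level] = ((status[sel] == 1).sum(), (status[sel] == 0).sum())
        ever = smoking.isin(("former", "current"))
        rows["ever"] = ((status[ever] == 1).sum(), (status[ever] == 0).sum())
        rows["total"] = ((status == 1).sum(), (status == 0).sum())
        return pd.DataFrame(rows, index=["cases", "controls"]).T.astype(int)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the cohort in the same TSV dialect :func:`load_cohort` reads
        (genotype counts, ``NA`` for missing, GSTM1 as present/null)."""
        out = self.table.copy()
        for p in self.polymorphisms:
            col = out[p].astype(object)
            if p == DELETION_COLUMN:
                col = col.map(lambda g: MISSING_TOKEN if g == MISSING
                              else _DELETION_LABELS[int(g)])
            else:
                col = col.map(lambda g: MISSING_TOKEN if g == MISSING else str(int(g)))
            out[p] = col
        out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)

    def validation_report(self, path: str | Path | None = None) -> dict:
        report = dict(self.validation)
        report.setdefault("n_subjects", self.n_subjects)
        report.setdefault("n_cases", self.n_cases)
        report.setdefault("n_controls", self.n_controls)
        report["strata"] = {
            k: {"cases": int(v["cases"]), "controls": int(v["controls"])}
            for k, v in self.stratum_counts().iterrows()
        }
        report["missing_per_polymorphism"] = {
            p: int((self.table[p] == MISSING).sum()) for p in self.polymorphisms
        }
        if path is not None:
            Path(path).write_text(json.dumps(report, indent=2))
        return report


# ---------------------------------------------------------------------------
# loading


def _map_snp_alleles(raw: pd.Series, status: pd.Series) -> tuple[pd.Series, dict[int, str]]:
    """Map 'X/Y' allele strings to minor-allele counts, orienting by the
    minor allele among control chromosomes."""
    tokens = raw.where(raw != MISSING_TOKEN)
    split = tokens.str.split("/", expand=True)
    if split.shape[1] != 2:
        raise CohortValidationError(f"column {raw.name!r}: genotype strings must be 'X/Y'")
    ctrl = split[status.to_numpy() == 0]
    counts = pd.concat([ctrl[0], ctrl[1]]).value_counts()
    alleles = sorted(counts.index)
    if len(alleles) > 2:
        raise CohortValidationError(f"column {raw.name!r}: more than two alleles {alleles}")
    if len(alleles) == 2:
        # minor = less frequent in controls; ties broken alphabetically
        minor = min(alleles, key=lambda a: (counts[a], a))
    else:
        minor = alleles[0]
    major = next((a for a in alleles if a != minor), minor)
    codes = split.isin([minor]).sum(axis=1).astype(np.int8)
    codes[tokens.isna()] = MISSING
    amap = {0: f"{major}/{major}", 1: f"{major}/{minor}", 2: f"{minor}/{minor}"}
    return codes, amap


def cohort_from_dataframe(
    df: pd.DataFrame,
    dialect: str = "count",
    polymorphisms: Sequence[str] = POLYMORPHISMS,
) -> CohortData:
    """Validate a raw subject table and build a :class:`CohortData`.

    ``dialect`` is ``"count"`` (SNPs as 0/1/2) or ``"alleles"`` (SNPs as
    'X/Y' strings).  The GSTM1 column accepts present/null (or 0/1) in both
    dialects.  Rows with out-of-domain codes are rejected and listed in the
    validation report; structural problems raise :class:`CohortFormatError`.
    """
    if dialect not in ("count", "alleles"):
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    missing_cols = [c for c in REQUIRED_COLUMNS + tuple(polymorphisms)
                    if c not in df.columns]
    if missing_cols:
        raise CohortFormatError(f"missing mandatory columns: {missing_cols}")

    df = df.copy().reset_index(drop=True)
    bad: dict[int, list[str]] = {}

    def flag(rows: pd.Index, reason: str) -> None:
        for r in rows:
            bad.setdefault(int(r), []).append(reason)

    status = pd.to_numeric(df["status"], errors="coerce")
    flag(df.index[~status.isin([0, 1])], "status not in {0,1}")
    df["status"] = status

    smoking = df["smoking"].astype(str)
    flag(df.index[~smoking.isin(SMOKING_LEVELS)], f"smoking not in {SMOKING_LEVELS}")
    df["smoking"] = smoking

    allele_maps: dict[str, dict[int, str]] = {}
    for p in polymorphisms:
        raw = df[p].astype(str).str.strip()
        if p == DELETION_COLUMN:
            mapped = raw.map(lambda t: _DELETION_TOKENS.get(t, MISSING if t == MISSING_TOKEN else None))
            flag(df.index[mapped.isna()], f"{p}: unmappable code")
            df[p] = mapped.fillna(MISSING).astype(np.int8)
        elif dialect == "count":
            num = pd.to_numeric(raw.where(raw != MISSING_TOKEN), errors="coerce")
            ok = num.isin([0, 1, 2]) | (raw == MISSING_TOKEN)
            flag(df.index[~ok], f"{p}: genotype not in {{0,1,2,NA}}")
            df[p] = num.where(ok).fillna(MISSING).astype(np.int8)
        else:
            shaped = (raw == MISSING_TOKEN) | raw.str.fullmatch(r"[A-Za-z]/[A-Za-z]")
            flag(df.index[~shaped], f"{p}: unmappable genotype string")
            cleaned = raw.where(shaped, MISSING_TOKEN)
            codes, amap = _map_snp_alleles(cleaned.rename(p), pd.Series(status))
            df[p] = codes
            allele_maps[p] = amap
    if allele_maps:
        allele_maps[DELETION_COLUMN] = dict(_DELETION_LABELS)

    rejected = sorted(bad)
    kept = df.drop(index=rejected).reset_index(drop=True)
    if kept.empty:
        raise CohortValidationError(
            "no valid rows; offending rows: "
            + "; ".join(f"row {r}: {', '.join(bad[r])}" for r in rejected[:20])
        )
    kept["status"] = kept["status"].astype(np.int8)
    kept["age"] = pd.to_numeric(kept["age"], errors="coerce")

    validation = {
        "rows_read": int(len(df)),
        "rows_rejected": [{"row": r, "reasons": bad[r]} for r in rejected],
        "dialect": dialect,
    }
    return CohortData(kept, tuple(polymorphisms),
                      allele_maps=allele_maps or None, validation=validation)


def load_cohort(
    path: str | Path,
    dialect: str = "count",
    polymorphisms: Sequence[str] = POLYMORPHISMS,
) -> CohortData:
    """Read a tab-separated cohort table (UTF-8, header row, ``NA`` missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return cohort_from_dataframe(df, dialect=dialect, polymorphisms=polymorphisms)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Chi-square (1 df) test of Hardy-Weinberg proportions.

    ``genotype_counts`` is ``(n_AA, n_Aa, n_aa)``.  The allele frequency is
    estimated from the sample; expected counts are n*(p^2, 2pq, q^2).  A
    sample that is monomorphic after estimation (p in {0, 1}) fits HWE
    perfectly by construction and returns ``(0.0, 1.0)``.
    """
    n_aa_hom, n_het, n_vv = (int(c) for c in genotype_counts)
    if min(n_aa_hom, n_het, n_vv) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_vv
    if n == 0:
        raise ValueError("all genotype counts are zero")
    q = (n_het + 2 * n_vv) / (2 * n)
    if q in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2])
    observed = np.array([n_aa_hom, n_het, n_vv], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_report(cohort: CohortData) -> pd.DataFrame:
    """Per-SNP HWE chi-square and p, separately for cases and controls."""
    rows = []
    for p in cohort.polymorphisms:
        if cohort.domains[p] != BIALLELIC_DOMAIN:
            continue
        g = cohort.genotypes(p)
        for group, sel in (("cases", cohort.status == 1), ("controls", cohort.status == 0)):
            gg = g[sel]
            gg = gg[gg != MISSING]
            counts = [(gg == k).sum() for k in (0, 1, 2)]
            if sum(counts) == 0:
                continue
            chi2, pval = hwe_test(counts)
            rows.append({"polymorphism": p, "group": group,
                         "n_AA": counts[0], "n_Aa": counts[1], "n_aa": counts[2],
                         "chi2": chi2, "p": pval})
    return pd.DataFrame(rows)
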