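"""Binary risk indicators and k-way genotype combinations.

A *risk indicator* recodes one polymorphism as a binary exposure: a subset
of its genotype codes is designated the "risk" (exposed) group.  For a
biallelic SNP coded by variant-allele count (0/1/2) only the four
order-respecting splits are admissible —

    {2}      homozygous-variant   (recessive coding)
    {1, 2}   variant carrier      (dominant coding)
    {0, 1}   complement of {2}
    {0}      complement of {1, 2}

— i.e. the dominant and recessive codings of either allele.  Splits that
break the genotype ordering, such as {0, 2} vs {1}, are not candidates.
A binary polymorphism (e.g. a homozygous gene deletion scored
present/null) admits exactly the two singleton splits.

A *combination* is a conjunction of indicators on distinct polymorphisms:
a subject is exposed iff every member indicator is true.  With six SNPs
and one binary polymorphism this yields 26 one-way, 288 two-way and 1,760
three-way candidate exposures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Mapping, Sequence

import numpy as np

#: genotype code for a missing observation
MISSING = -1

BIALLELIC_DOMAIN: tuple[int, ...] = (0, 1, 2)
BINARY_DOMAIN: tuple[int, ...] = (0, 1)

# admissible risk sets per domain: contiguous, non-empty, proper
_RISK_SETS = {
    BIALLELIC_DOMAIN: ((0,), (0, 1), (1, 2), (2,)),
    BINARY_DOMAIN: ((0,), (1,)),
}


@dataclass(frozen=True, order=True)
class RiskIndicator:
    """One polymorphism together with its designated risk-genotype subset."""

    polymorphism: str
    risk_set: tuple[int, ...]
    domain: tuple[int, ...] = field(default=BIALLELIC_DOMAIN, compare=False)

    def __post_init__(self) -> None:
        rs = tuple(sorted(self.risk_set))
        object.__setattr__(self, "risk_set", rs)
        if not rs or set(rs) == set(self.domain):
            raise ValueError(
                f"risk set {rs} must be a non-empty proper subset of {self.domain}"
            )
        if not set(rs) <= set(self.domain):
            raise ValueError(f"risk set {rs} outside genotype domain {self.domain}")
        # contiguity in the 0 <= 1 <= 2 ordering
        if rs[-1] - rs[0] + 1 != len(rs):
            raise ValueError(f"risk set {rs} is not order-respecting")

    @property
    def key(self) -> str:
        codes = "".join(str(g) for g in self.risk_set)
        return f"{self.polymorphism}:{codes}"

    def complement(self) -> "RiskIndicator":
        rest = tuple(g for g in self.domain if g not in self.risk_set)
        return RiskIndicator(self.polymorphism, rest, self.domain)

    def is_exposed(self, genotypes: np.ndarray) -> np.ndarray:
        """Boolean exposure per subject; missing genotypes map to False."""
        return np.isin(genotypes, self.risk_set)

    def label(self, allele_map: Mapping[int, str] | None = None) -> str:
        """Human-readable form, e.g. ``rs710521 [A/A, A/G]`` or ``GSTM1 null``."""
        if allele_map is None:
            codes = ", ".join(str(g) for g in self.risk_set)
            return f"{self.polymorphism} {{{codes}}}"
        parts = [allele_map[g] for g in self.risk_set]
        if self.domain == BINARY_DOMAIN and len(parts) == 1:
            return f"{self.polymorphism} {parts[0]}"
        return f"{self.polymorphism} [{', '.join(parts)}]"


def enumerate_indicators(
    polymorphism: str, domain: Sequence[int]
) -> list[RiskIndicator]:
    """All admissible indicators for one polymorphism, in deterministic order.

    Returns 4 indicators for a biallelic SNP and 2 for a binary polymorphism.
    """
    dom = tuple(domain)
    if dom not in _RISK_SETS:
        raise ValueError(f"unknown genotype domain {dom!r}")
    return [RiskIndicator(polymorphism, rs, dom) for rs in _RISK_SETS[dom]]


@dataclass(frozen=True)
class Combination:
    """A conjunction of risk indicators on distinct polymorphisms."""

    indicators: tuple[RiskIndicator, ...]

    def __post_init__(self) -> None:
        inds = tuple(sorted(self.indicators, key=lambda i: (i.polymorphism, i.risk_set)))
        object.__setattr__(self, "indicators", inds)
        polys = [i.polymorphism for i in inds]
        if len(polys) < 1:
            raise ValueError("a combination needs at least one indicator")
        if len(set(polys)) != len(polys):
            raise ValueError(f"indicators must reference distinct polymorphisms: {polys}")

    @property
    def order(self) -> int:
        return len(self.indicators)

    @property
    def polymorphisms(self) -> tuple[str, ...]:
        return tuple(i.polymorphism for i in self.indicators)

    @property
    def key(self) -> str:
        return "|".join(i.key for i in self.indicators)

    def label(self, allele_maps: Mapping[str, Mapping[int, str]] | None = None) -> str:
        parts = []
        for ind in self.indicators:
            amap = allele_maps.get(ind.polymorphism) if allele_maps else None
            parts.append(ind.label(amap))
        return " x ".join(parts)

    def exposure(
        self, genotypes: Mapping[str, np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray]:
        """``(exposed, defined)`` boolean arrays over subjects.

        A subject with a missing genotype at any member polymorphism has
        undefined exposure (``defined`` False); its ``exposed`` entry is
        forced False.  The result does not depend on indicator order.
        """
        first = genotypes[self.indicators[0].polymorphism]
        exposed = np.ones(len(first), dtype=bool)
        defined = np.ones(len(first), dtype=bool)
        for ind in self.indicators:
            g = np.asarray(genotypes[ind.polymorphism])
            defined &= g != MISSING
            exposed &= ind.is_exposed(g)
        exposed &= defined
        return exposed, defined

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


def count_combinations(n_snps: int, n_binary: int, k: int) -> int:
    """Number of distinct k-way combinations over ``n_snps`` biallelic SNPs
    (4 indicators each) and ``n_binary`` binary polymorphisms (2 each).

    Equals sum_j C(n_snps, k-j) 4^(k-j) C(n_binary, j) 2^j — e.g. 288 for
    (6, 1, 2) and 1,760 for (6, 1, 3).
    """
    total = n_snps + n_binary
    if k < 1 or k > total:
        raise ValueError(f"k={k} outside 1..{total}")
    return sum(
        comb(n_snps, k - j) * 4 ** (k - j) * comb(n_binary, j) * 2**j
        for j in range(0, min(k, n_binary) + 1)
        if k - j <= n_snps
    )


def enumerate_combinations(
    domains: Mapping[str, Sequence[int]], k: int
) -> Iterator[Combination]:
    """Exhaustively enumerate all k-way combinations, deterministically.

    ``domains`` maps polymorphism name to its genotype domain; iteration
    order of ``domains`` fixes the enumeration order.
    """
    names = list(domains)
    if k < 1 or k > len(names):
        raise ValueError(f"k={k} outside 1..{len(names)}")
    per_poly = {name: enumerate_indicators(name, domains[name]) for name in names}
    for chosen in itertools.combinations(names, k):
        for inds in itertools.product(*(per_poly[name] for name in chosen)):
            yield Combination(tuple(inds))
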