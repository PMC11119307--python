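"""COX-2 -765G>C genotype calling from PCR-RFLP fragment patterns.

The assay amplifies a 228-bp promoter fragment spanning the -765G>C SNP.
The restriction enzyme (Fau I) cuts only when the G allele is present,
yielding 161-bp and 67-bp fragments; the C allele leaves the amplicon uncut.
Hence GG -> {161, 67}, CC -> {228}, GC -> {228, 161, 67}. Because the CC
genotype is rare, analyses pool C carriers (GC + CC) against GG.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AMPLICON_BP",
    "CUT_FRAGMENTS_BP",
    "Genotype",
    "PooledGenotype",
    "FragmentPattern",
    "GenotypeFrequencies",
    "NoCallError",
    "expected_fragments",
    "call_genotype",
    "pool_c_carriers",
    "genotype_frequencies",
    "hwe_chi_square",
]

AMPLICON_BP = 228
CUT_FRAGMENTS_BP = (161, 67)  # 161 + 67 == 228, enforced below


class Genotype(str, enum.Enum):
    GG = "GG"
    GC = "GC"
    CC = "CC"


class PooledGenotype(str, enum.Enum):
    GG = "GG"
    C_CARRIER = "C_carrier"


class NoCallError(ValueError):
    """Fragment pattern not produced by the -765G>C RFLP assay."""


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of restriction-fragment lengths in base pairs."""

    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("fragment pattern must be non-empty")
        if any(l <= 0 or l > AMPLICON_BP for l in self.lengths):
            raise ValueError(f"fragment lengths must lie in 1..{AMPLICON_BP} bp")
        object.__setattr__(self, "lengths", tuple(sorted(self.lengths, reverse=True)))

    def as_multiset(self) -> Counter:
        return Counter(self.lengths)


_GENOTYPE_PATTERNS: dict[Genotype, tuple[int, ...]] = {
    Genotype.GG: CUT_FRAGMENTS_BP,
    Genotype.CC: (AMPLICON_BP,),
    Genotype.GC: (AMPLICON_BP,) + CUT_FRAGMENTS_BP,
}

assert sum(CUT_FRAGMENTS_BP) == AMPLICON_BP, "digestion must conserve amplicon length"


def expected_fragments(call: Genotype | str) -> FragmentPattern:
    """Fragment pattern the assay produces for a genotype."""
    return FragmentPattern(_GENOTYPE_PATTERNS[Genotype(call)])


def call_genotype(pattern: FragmentPattern | Iterable[int], tolerance_bp: int = 0) -> Genotype:
    """Invert expected_fragments: map an observed pattern to a genotype call.

    With ``tolerance_bp`` > 0 each observed length may deviate by up to that
    many bp from an expected length (for gel-estimated sizes); a pattern
    matching more than one genotype under the tolerance is a no-call. Any
    unrecognized pattern (including partial digests such as {228, 161})
    raises :class:`NoCallError` rather than defaulting.
    """
    if not isinstance(pattern, FragmentPattern):
        pattern = FragmentPattern(tuple(pattern))
    matches = [
        g
        for g, expected in _GENOTYPE_PATTERNS.items()
        if _pattern_matches(pattern.lengths, expected, tolerance_bp)
    ]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise NoCallError(f"unrecognized fragment pattern {pattern.lengths} bp")
    raise NoCallError(
        f"ambiguous fragment pattern {pattern.lengths} bp at tolerance ±{tolerance_bp}"
    )


def _pattern_matches(observed: Sequence[int], expected: Sequence[int], tol: int) -> bool:
    if len(observed) != len(expected):
        return False
    obs, exp = sorted(observed), sorted(expected)
    return all(abs(o - e) <= tol for o, e in zip(obs, exp))


def pool_c_carriers(call: Genotype | str) -> PooledGenotype:
    """Collapse GC and CC into a single C-carrier category."""
    call = Genotype(call)
    return PooledGenotype.GG if call is Genotype.GG else PooledGenotype.C_CARRIER


@dataclass(frozen=True)
class GenotypeFrequencies:
    n_GG: int
    n_GC: int
    n_CC: int

    @property
    def n(self) -> int:
        return self.n_GG + self.n_GC + self.n_CC

    @property
    def freq_GG(self) -> float:
        return self.n_GG / self.n

    @property
    def freq_GC(self) -> float:
        return self.n_GC / self.n

    @property
    def freq_CC(self) -> float:
        return self.n_CC / self.n

    @property
    def allele_C_freq(self) -> float:
        return (2 * self.n_CC + self.n_GC) / (2 * self.n)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "n_GG": self.n_GG,
            "n_GC": self.n_GC,
            "n_CC": self.n_CC,
            "freq_GG": self.freq_GG,
            "freq_GC": self.freq_GC,
            "freq_CC": self.freq_CC,
            "allele_C_freq": self.allele_C_freq,
        }


def genotype_frequencies(calls: Iterable[Genotype | str]) -> GenotypeFrequencies:
    """Genotype counts, proportions and the C-allele frequency."""
    counts = Counter(Genotype(c) for c in calls)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no genotype calls supplied")
    return GenotypeFrequencies(
        n_GG=counts[Genotype.GG], n_GC=counts[Genotype.GC], n_CC=counts[Genotype.CC]
    )


def hwe_chi_square(freqs: GenotypeFrequencies):
    """One-df chi-square test of Hardy-Weinberg proportions.

    Compares observed genotype counts with the p^2, 2pq, q^2 expectations at
    the observed allele frequencies. A monomorphic sample (allele frequency
    0 or 1) fits HWE exactly; the statistic is defined as 0.

    Returns an association.TestResult.
    """
    from .association import TestResult  # local import to avoid a cycle

    n = freqs.n
    if n <= 0:
        raise ValueError("empty genotype sample")
    q = freqs.allele_C_freq
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return TestResult(statistic=0.0, df=1, p_value=1.0, test_name="HWE chi-square")
    observed = np.array([freqs.n_GG, freqs.n_GC, freqs.n_CC], dtype=float)
    expected = n * np.array([p * p, 2 * p * q, q * q])
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, df=1, p_value=p_value, test_name="HWE chi-square")
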