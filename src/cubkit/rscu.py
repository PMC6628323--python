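"""Relative synonymous codon usage.

RSCU of a codon is its observed count divided by the mean count over its
synonymous family, so each observed family sums to its size (2, 3, 4 or 6).
Representation thresholds: >=1.6 over-represented, <=0.6 under-represented,
with 1 the positive/negative boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genetics import (
    STANDARD_CODE,
    CodonCountTable,
    CubkitError,
    GeneticCode,
)

OVER_THRESHOLD = 1.6
UNDER_THRESHOLD = 0.6


class UnobservedProfileError(CubkitError):
    pass


class CensusError(CubkitError):
    pass


@dataclass
class RscuProfile:
    """RSCU values for the 59 sense codons.

    Codons of unobserved families carry NaN and the family is listed in
    ``unobserved_families``; downstream censuses refuse to run on such
    profiles instead of imputing.
    """

    values: dict[str, float]
    source: str  # single_sequence | pooled_counts | mean_of_sequences | external_table
    unobserved_families: frozenset[str] = frozenset()
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    def family_values(self, aa: str) -> dict[str, float]:
        return {c: self.values[c] for c in self.code.families[aa]}

    def preferred(self, aa: str) -> str:
        """Family argmax codon; ties broken lexicographically (and warned)."""
        if aa in self.unobserved_families:
            raise CensusError(f"family {aa} unobserved; no preferred codon")
        fam = self.family_values(aa)
        best = max(fam.values())
        tied = sorted(c for c, v in fam.items() if v == best)
        if len(tied) > 1:
            warnings.warn(
                f"RSCU tie in family {aa}: {tied}; reporting {tied[0]}",
                stacklevel=2,
            )
        return tied[0]

    def preferred_codons(self) -> dict[str, str]:
        return {aa: self.preferred(aa) for aa in self.code.families}

    def as_vector(self, codon_order: Sequence[str] | None = None) -> list[float]:
        order = codon_order or self.code.sense_codons
        return [self.values[c] for c in order]


@dataclass(frozen=True)
class CoincidenceReport:
    """Virus-vs-host preferred-codon comparison over the 18 families."""

    verdicts: Mapping[str, str]  # family -> coincidence | antagonism
    n_coincidence: int
    n_antagonism: int
    ending_census: Mapping[str, int]  # base -> count of preferred codons ending in it


def rscu_from_counts(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> RscuProfile:
    """RSCU_i = g_i / mean(g over family), per observed family."""
    values: dict[str, float] = {}
    unobserved: set[str] = set()
    for aa, codons in code.families.items():
        fam_counts = [counts.counts.get(c, 0) for c in codons]
        total = sum(fam_counts)
        if total == 0:
            unobserved.add(aa)
            for c in codons:
                values[c] = math.nan
            continue
        k = len(codons)
        for c, g in zip(codons, fam_counts):
            values[c] = g * k / total
    if len(unobserved) == len(code.families):
        raise UnobservedProfileError("no synonymous codons observed")
    return RscuProfile(
        values=values,
        source="single_sequence",
        unobserved_families=frozenset(unobserved),
        code=code,
    )


def mean_rscu(profiles: Sequence[RscuProfile]) -> RscuProfile:
    """Codon-wise arithmetic mean of profiles sharing a family structure.

    A family unobserved in any input profile is unobserved in the mean.
    """
    if not profiles:
        raise UnobservedProfileError("mean_rscu of empty profile list")
    code = profiles[0].code
    unobserved = frozenset().union(*(p.unobserved_families for p in profiles))
    values = {
        c: (
            math.nan
            if code.codon_to_family[c] in unobserved
            else sum(p.values[c] for p in profiles) / len(profiles)
        )
        for c in code.sense_codons
    }
    return RscuProfile(
        values=values,
        source="mean_of_sequences",
        unobserved_families=unobserved,
        code=code,
    )


def representation_calls(
    profile: RscuProfile,
    over: float = OVER_THRESHOLD,
    under: float = UNDER_THRESHOLD,
) -> dict[str, str]:
    """Classify each codon as over / under / positive / negative / neutral.

    Boundary values count as over/under (>= and <=), which is what makes
    a codon sitting exactly at 1.6 an over-represented call.
    """
    calls: dict[str, str] = {}
    for codon, v in profile.values.items():
        if math.isnan(v):
            calls[codon] = "unobserved"
        elif v >= over:
            calls[codon] = "over"
        elif v <= under:
            calls[codon] = "under"
        elif v > 1.0:
            calls[codon] = "positive"
        elif v < 1.0:
            calls[codon] = "negative"
        else:
            calls[codon] = "neutral"
    return calls


def ending_census(profile: RscuProfile) -> dict[str, int]:
    """Third-position base counts of each family's preferred codon."""
    if profile.unobserved_families:
        raise CensusError(
            "unobserved families: " + ", ".join(sorted(profile.unobserved_families))
        )
    census = {b: 0 for b in "ACGT"}
    for aa in profile.code.families:
        census[profile.preferred(aa)[2]] += 1
    return census


def coincidence_analysis(
    virus: RscuProfile, host: RscuProfile
) -> CoincidenceReport:
    """A family is a coincidence iff virus and host prefer the same codon."""
    if virus.code.families.keys() != host.code.families.keys():
        raise CubkitError("mismatched family structures")
    if virus.unobserved_families or host.unobserved_families:
        raise CensusError("coincidence analysis needs all 18 families observed")
    verdicts = {
        aa: (
            "coincidence"
            if virus.preferred(aa) == host.preferred(aa)
            else "antagonism"
        )
        for aa in virus.code.families
    }
    n_c = sum(v == "coincidence" for v in verdicts.values())
    return CoincidenceReport(
        verdicts=verdicts,
        n_coincidence=n_c,
        n_antagonism=len(verdicts) - n_c,
        ending_census=ending_census(virus),
    )
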