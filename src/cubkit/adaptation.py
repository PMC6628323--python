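"""Host-adaptation indices: CAI, RCDI and the similarity index SiD.

CAI is the Sharp & Li geometric mean of relative-adaptiveness weights
(w = RSCU / family-max RSCU) over a gene's synonymous codons. RCDI is the
Puigbo average of within-amino-acid codon-frequency ratios, gene versus
host. SiD is the cosine-based distance D = (1 - R) / 2 between two
59-dimensional RSCU vectors.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genetics import (
    STANDARD_CODE,
    CodonCountTable,
    CubkitError,
    GeneticCode,
)
from .rscu import RscuProfile

logger = logging.getLogger(__name__)

#: Floor, in pseudo-occurrences, applied to zero-usage host codons so that
#: CAI/RCDI stay finite on finite reference tables.
ZERO_USAGE_FLOOR = 0.5


class IncompleteReferenceError(CubkitError):
    pass


@dataclass
class HostReference:
    """A host codon-usage reference with derived CAI/RCDI machinery.

    ``family_freq`` holds within-amino-acid relative codon frequencies
    (summing to 1 per family) and ``w`` the relative-adaptiveness weights
    (family max = 1). Zero-usage codons are floored (logged) so logarithms
    stay finite.
    """

    name: str
    rscu: RscuProfile
    family_freq: dict[str, float] = field(default_factory=dict)
    w: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.family_freq:
            self._derive()

    def _derive(self) -> None:
        code = self.rscu.code
        if self.rscu.unobserved_families:
            raise IncompleteReferenceError(
                f"{self.name}: unobserved families "
                f"{sorted(self.rscu.unobserved_families)} in reference"
            )
        for aa, codons in code.families.items():
            vals = [self.rscu.values[c] for c in codons]
            if any(v == 0.0 for v in vals):
                floored = [c for c, v in zip(codons, vals) if v == 0.0]
                logger.warning(
                    "%s: zero-usage codon(s) %s floored at %s pseudo-occurrences",
                    self.name, floored, ZERO_USAGE_FLOOR,
                )
                # RSCU values are proportional to counts within a family, so
                # flooring them directly implements the occurrence floor.
                vals = [v if v > 0.0 else ZERO_USAGE_FLOOR for v in vals]
            total = sum(vals)
            vmax = max(vals)
            for c, v in zip(codons, vals):
                self.family_freq[c] = v / total
                self.w[c] = v / vmax


_KAZUSA_FIELD = re.compile(
    r"([ACGTU]{3})\s+([0-9]*\.?[0-9]+)(?:\s*\(\s*([0-9]+)\s*\))?"
)


def parse_kazusa(text: str, code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
    """Parse codon-usage-database style text into per-codon usage numbers.

    Accepts the common layout of ``CODON freq-per-1000 (count)`` fields,
    several per line, with either U or T alphabets. Counts are used when
    present, per-1000 frequencies otherwise.
    """
    usage: dict[str, float] = {}
    for codon_raw, per_thousand, count in _KAZUSA_FIELD.findall(text):
        codon = codon_raw.upper().replace("U", "T")
        usage[codon] = float(count) if count else float(per_thousand)
    if not usage:
        raise IncompleteReferenceError("no codon usage fields recognised in input")
    return usage


def reference_from_usage(
    name: str,
    usage: Mapping[str, float],
    code: GeneticCode = STANDARD_CODE,
) -> HostReference:
    """Build a HostReference from absolute or per-1000 codon usage numbers."""
    missing = [c for c in code.sense_codons if c not in usage]
    if missing:
        raise IncompleteReferenceError(
            f"{name}: usage table missing sense codons (e.g. {missing[:3]})"
        )
    values: dict[str, float] = {}
    for aa, codons in code.families.items():
        fam = [usage[c] for c in codons]
        total = sum(fam)
        if total == 0:
            raise IncompleteReferenceError(f"{name}: family {aa} has zero total usage")
        k = len(codons)
        for c, u in zip(codons, fam):
            values[c] = u * k / total
    profile = RscuProfile(values=values, source="external_table", code=code)
    return HostReference(name=name, rscu=profile)


def load_host_reference(
    source: str, code: GeneticCode = STANDARD_CODE
) -> HostReference:
    """Load a host reference from a fixture name, an RSCU TSV, or a
    Kazusa-style codon usage text file."""
    from .fixtures import FIXTURE_NAMES, load_fixture, load_rscu_table

    if source in FIXTURE_NAMES:
        return HostReference(name=source, rscu=load_fixture(source, code))
    text = open(source).read()
    if "\tcodon\t" in text.splitlines()[0] + "\t" or text.startswith("aa\t") or text.startswith("codon\t"):
        return HostReference(name=str(source), rscu=load_rscu_table(source, code))
    return reference_from_usage(str(source), parse_kazusa(text, code), code)


def cai(counts: CodonCountTable, host: HostReference) -> float:
    """Geometric mean of host relative-adaptiveness weights over the gene."""
    code = host.rscu.code
    log_sum = 0.0
    n = 0
    for codon, g in counts.counts.items():
        if not code.is_sense(codon) or g == 0:
            continue
        log_sum += g * math.log(host.w[codon])
        n += g
    if n == 0:
        raise CubkitError("no synonymous codons; CAI undefined")
    return math.exp(log_sum / n)


def rcdi(counts: CodonCountTable, host: HostReference) -> float:
    """Average ratio of within-amino-acid codon frequencies, gene vs host."""
    code = host.rscu.code
    total = 0.0
    n = 0
    for aa, codons in code.families.items():
        fam_counts = [counts.counts.get(c, 0) for c in codons]
        fam_total = sum(fam_counts)
        if fam_total == 0:
            continue
        for c, g in zip(codons, fam_counts):
            if g == 0:
                continue
            cif_virus = g / fam_total
            total += (cif_virus / host.family_freq[c]) * g
            n += g
    if n == 0:
        raise CubkitError("no synonymous codons; RCDI undefined")
    return total / n


@dataclass(frozen=True)
class AdaptationScores:
    id: str
    host: str
    cai: float
    rcdi: float


def adaptation_scores(
    seq_id: str, counts: CodonCountTable, host: HostReference
) -> AdaptationScores:
    return AdaptationScores(
        id=seq_id, host=host.name, cai=cai(counts, host), rcdi=rcdi(counts, host)
    )


def sid(virus: RscuProfile, host: RscuProfile) -> float:
    """Similarity-index distance D = (1 - cosine(virus, host)) / 2."""
    order = virus.code.sense_codons
    a = np.asarray(virus.as_vector(order), dtype=float)
    b = np.asarray(host.as_vector(order), dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise CubkitError("SiD needs complete 59-codon profiles")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise CubkitError("zero-norm RSCU vector; SiD undefined")
    r = float(np.dot(a, b) / (na * nb))
    return (1.0 - r) / 2.0
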