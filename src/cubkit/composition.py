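"""Nucleotide and codon-position composition statistics.

Silent-site quantities (A3s/T3s/G3s/C3s, GC3s) are computed over third
positions of synonymous codons only; GC1/GC2 use the first/second positions
of that same codon set, and GC12 is their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

from .genetics import (
    STANDARD_CODE,
    CodingSequence,
    CubkitError,
    GeneticCode,
    _is_clean_codon,
)


class UndefinedCompositionError(CubkitError):
    """Raised when a sequence has no synonymous codons to measure."""


@dataclass(frozen=True)
class CompositionSummary:
    id: str
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    A3s: float
    T3s: float
    G3s: float
    C3s: float
    GC1: float
    GC2: float
    GC12: float
    GC3s: float
    AT_total: float
    GC_total: float

    def as_dict(self) -> dict:
        return asdict(self)


def composition_summary(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> CompositionSummary:
    nt = seq.nucleotides
    n_acgt = sum(nt.count(b) for b in "ACGT")
    if n_acgt == 0:
        raise UndefinedCompositionError(f"{seq.id}: no unambiguous bases")
    pct = {b: 100.0 * nt.count(b) / n_acgt for b in "ACGT"}

    syn = [
        c for c in seq.codons if _is_clean_codon(c) and code.is_sense(c)
    ]
    if not syn:
        raise UndefinedCompositionError(
            f"{seq.id}: no synonymous codons (Met/Trp/stop only?)"
        )
    n = len(syn)
    third = [c[2] for c in syn]
    p3 = {b: 100.0 * third.count(b) / n for b in "ACGT"}
    gc1 = sum(c[0] in "GC" for c in syn) / n
    gc2 = sum(c[1] in "GC" for c in syn) / n
    gc3s = sum(b in "GC" for b in third) / n
    gc_total = sum(nt.count(b) for b in "GC") / n_acgt

    return CompositionSummary(
        id=seq.id,
        pct_A=pct["A"], pct_T=pct["T"], pct_G=pct["G"], pct_C=pct["C"],
        A3s=p3["A"], T3s=p3["T"], G3s=p3["G"], C3s=p3["C"],
        GC1=gc1, GC2=gc2, GC12=(gc1 + gc2) / 2.0, GC3s=gc3s,
        AT_total=1.0 - gc_total, GC_total=gc_total,
    )


def composition_batch(
    seqs: Iterable[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> list[dict]:
    """Per-sequence composition rows in input order; failures become flagged
    rows rather than aborting the batch."""
    rows: list[dict] = []
    for seq in seqs:
        try:
            rows.append({**composition_summary(seq, code).as_dict(), "status": "ok"})
        except CubkitError as err:
            rows.append({"id": seq.id, "status": "error", "reason": str(err)})
    return rows
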