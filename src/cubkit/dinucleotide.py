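"""Dinucleotide odds ratios.

P_xy = f_xy / (f_x * f_y) over overlapping dinucleotides; >1.23 is called
over-represented and <0.78 under-represented. Linear counting uses the
L-1 overlapping pairs of the CDS string; circular counting adds the
last-to-first wrap (the viral genome is circular).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .genetics import BASES, CodingSequence, CubkitError

DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, BASES))
OVER_THRESHOLD = 1.23
UNDER_THRESHOLD = 0.78


@dataclass(frozen=True)
class DinucleotideProfile:
    id: str
    odds: dict[str, float]
    calls: dict[str, str]  # over | normal | under
    counting_mode: str


def _call(p: float) -> str:
    if p > OVER_THRESHOLD:
        return "over"
    if p < UNDER_THRESHOLD:
        return "under"
    return "normal"


def dinucleotide_odds(
    seq: CodingSequence | str, mode: str = "linear"
) -> DinucleotideProfile:
    """Sixteen odds ratios for one sequence; non-ACGT positions excluded."""
    if isinstance(seq, CodingSequence):
        seq_id, nt = seq.id, seq.nucleotides
    else:
        seq_id, nt = "seq", seq.upper().replace("U", "T")
    if len(nt) < 2:
        raise CubkitError(f"{seq_id}: need at least 2 bases")
    if mode not in ("linear", "circular"):
        raise ValueError(f"unknown counting mode {mode!r}")

    base_n = {b: nt.count(b) for b in BASES}
    n_bases = sum(base_n.values())
    f1 = {b: base_n[b] / n_bases for b in BASES}

    pairs = [nt[i : i + 2] for i in range(len(nt) - 1)]
    if mode == "circular":
        pairs.append(nt[-1] + nt[0])
    pairs = [p for p in pairs if p in DINUCLEOTIDES]
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise CubkitError(f"{seq_id}: no unambiguous dinucleotides")

    odds: dict[str, float] = {}
    for d in DINUCLEOTIDES:
        fxy = pairs.count(d) / n_pairs
        expected = f1[d[0]] * f1[d[1]]
        odds[d] = fxy / expected if expected > 0 else 0.0
    return DinucleotideProfile(
        id=seq_id,
        odds=odds,
        calls={d: _call(p) for d, p in odds.items()},
        counting_mode=mode,
    )


def dinucleotide_batch(
    seqs: Iterable[CodingSequence], mode: str = "linear"
) -> tuple[list[DinucleotideProfile], dict[str, dict[str, float]]]:
    """Per-sequence profiles plus mean +/- sample SD per dinucleotide."""
    profiles = [dinucleotide_odds(s, mode) for s in seqs]
    if not profiles:
        raise CubkitError("empty batch")
    summary: dict[str, dict[str, float]] = {}
    for d in DINUCLEOTIDES:
        vals = np.array([p.odds[d] for p in profiles])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary[d] = {
            "mean": float(vals.mean()),
            "sd": sd,
            "call": _call(float(vals.mean())),
        }
    return profiles, summary
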