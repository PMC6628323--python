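"""Synthetic in-frame CDS generation with controlled codon-usage structure.

Sequences are sampled codon-by-codon: an amino acid from ``aa_weights``,
then a codon from that family's weight vector. Weights come from one of
three sources, in precedence order: explicit ``family_codon_weights``, a
``gc3_target`` (within each family, probability mass ``gc3_target`` goes to
the G/C-ending codons), or a Dirichlet draw sharpened by
``bias_concentration`` (None = uniform usage). Stop codons never occur
because families contain none.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genetics import STANDARD_CODE, CodingSequence, CubkitError, GeneticCode


class InfeasibleTargetError(CubkitError):
    pass


@dataclass
class GeneratorSpec:
    n_sequences: int = 1
    n_codons: int = 1000
    aa_weights: Mapping[str, float] | None = None  # default: uniform over 18 families
    family_codon_weights: Mapping[str, Mapping[str, float]] | None = None
    gc3_target: float | None = None
    bias_concentration: float | None = None
    seed: int = 0
    include_met_trp: bool = False

    def spec_hash(self) -> str:
        payload = {
            "n_sequences": self.n_sequences,
            "n_codons": self.n_codons,
            "aa_weights": dict(self.aa_weights) if self.aa_weights else None,
            "family_codon_weights": (
                {a: dict(w) for a, w in self.family_codon_weights.items()}
                if self.family_codon_weights
                else None
            ),
            "gc3_target": self.gc3_target,
            "bias_concentration": self.bias_concentration,
            "seed": self.seed,
            "include_met_trp": self.include_met_trp,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:10]


def _resolve_aa_weights(
    spec: GeneratorSpec, code: GeneticCode
) -> tuple[list[str], np.ndarray]:
    if spec.aa_weights is not None:
        aas = sorted(spec.aa_weights)
        probs = np.array([spec.aa_weights[a] for a in aas], dtype=float)
    else:
        aas = sorted(code.families)
        if spec.include_met_trp:
            aas = sorted(aas + ["M", "W"])
        probs = np.ones(len(aas))
    if probs.sum() <= 0 or (probs < 0).any():
        raise CubkitError("amino-acid weights must be non-negative and sum > 0")
    return aas, probs / probs.sum()


def _gc3_family_weights(
    aa: str, codons: Sequence[str], target: float
) -> np.ndarray:
    """Split probability mass ``target`` over G/C-ending codons, uniformly
    within each class."""
    is_gc = np.array([c[2] in "GC" for c in codons])
    n_gc, n_at = int(is_gc.sum()), int((~is_gc).sum())
    if n_gc == 0 and target > 0:
        raise InfeasibleTargetError(
            f"family {aa} has no G/C-ending codon; gc3_target {target} infeasible"
        )
    if n_at == 0 and target < 1:
        raise InfeasibleTargetError(
            f"family {aa} has no A/T-ending codon; gc3_target {target} infeasible"
        )
    w = np.empty(len(codons))
    w[is_gc] = target / n_gc if n_gc else 0.0
    w[~is_gc] = (1.0 - target) / n_at if n_at else 0.0
    return w


def _resolve_family_weights(
    spec: GeneratorSpec,
    aas: Sequence[str],
    code: GeneticCode,
    rng: np.random.Generator,
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    if spec.gc3_target is not None and not 0.0 <= spec.gc3_target <= 1.0:
        raise InfeasibleTargetError(f"gc3_target {spec.gc3_target} outside [0, 1]")
    out: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa in aas:
        if aa == "M":
            out[aa] = (("ATG",), np.ones(1))
            continue
        if aa == "W":
            out[aa] = (("TGG",), np.ones(1))
            continue
        codons = code.families[aa]
        if spec.family_codon_weights is not None and aa in spec.family_codon_weights:
            given = spec.family_codon_weights[aa]
            w = np.array([given.get(c, 0.0) for c in codons], dtype=float)
            if w.sum() <= 0:
                raise CubkitError(f"family {aa}: weight vector sums to 0")
            w = w / w.sum()
        elif spec.gc3_target is not None:
            w = _gc3_family_weights(aa, codons, spec.gc3_target)
        elif spec.bias_concentration is not None:
            w = rng.dirichlet(np.full(len(codons), spec.bias_concentration))
        else:
            w = np.full(len(codons), 1.0 / len(codons))
        out[aa] = (codons, w)
    return out


def generate(
    spec: GeneratorSpec, code: GeneticCode = STANDARD_CODE
) -> tuple[list[CodingSequence], dict]:
    """Sample sequences per the spec; returns (sequences, ground truth).

    Ground truth records the resolved amino-acid and per-family codon
    weights and the expected GC3, so tests can compare realized statistics
    against what the generator intended.
    """
    if spec.n_codons < 1 or spec.n_sequences < 0:
        raise CubkitError("n_codons must be >= 1 and n_sequences >= 0")
    rng = np.random.default_rng(spec.seed)
    aas, aa_probs = _resolve_aa_weights(spec, code)
    fam = _resolve_family_weights(spec, aas, code, rng)

    # expected GC3 over synonymous codons only
    syn_mask = np.array([a not in ("M", "W") for a in aas])
    syn_probs = aa_probs[syn_mask]
    expected_gc3 = 0.0
    if syn_probs.sum() > 0:
        syn_probs = syn_probs / syn_probs.sum()
        for p_aa, aa in zip(syn_probs, np.array(aas)[syn_mask]):
            codons, w = fam[aa]
            expected_gc3 += p_aa * sum(
                wi for c, wi in zip(codons, w) if c[2] in "GC"
            )

    tag = spec.spec_hash()
    seqs: list[CodingSequence] = []
    for i in range(spec.n_sequences):
        aa_idx = rng.choice(len(aas), size=spec.n_codons, p=aa_probs)
        codons = np.empty(spec.n_codons, dtype="<U3")
        for j, aa in enumerate(aas):
            pos = np.flatnonzero(aa_idx == j)
            if pos.size == 0:
                continue
            fam_codons, w = fam[aa]
            picks = rng.choice(len(fam_codons), size=pos.size, p=w)
            codons[pos] = np.array(fam_codons, dtype="<U3")[picks]
        seqs.append(CodingSequence(f"sim_{tag}_{i:04d}", "".join(codons)))

    truth = {
        "spec_hash": tag,
        "aa_weights": {a: float(p) for a, p in zip(aas, aa_probs)},
        "family_codon_weights": {
            aa: {c: float(wi) for c, wi in zip(codons, w)}
            for aa, (codons, w) in fam.items()
        },
        "expected_gc3": float(expected_gc3),
        "seed": spec.seed,
        "generator": "numpy.random.default_rng(PCG64)",
    }
    return seqs, truth


# Families used by the neutrality panel: Lys (AAA/AAG) has GC12 = 0 and Ala
# (GCN) has GC12 = 1, so the amino-acid mix sets GC12 while each family's
# G/C-ending codon share sets GC3s independently.
_PANEL_LOW_GC12_AA = "K"
_PANEL_HIGH_GC12_AA = "A"


def generate_neutrality_panel(
    slope: float,
    intercept: float,
    gc3_range: tuple[float, float] = (0.2, 0.8),
    noise_sd: float = 0.01,
    n: int = 80,
    seed: int = 0,
    n_codons: int = 400,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[list[CodingSequence], list[dict]]:
    """Sequences whose (GC3s, GC12) scatter around gc12 = intercept + slope*gc3.

    Returns (sequences, truth rows) where each truth row holds the drawn
    true gc3 and the noised target gc12 for that sequence.
    """
    lo, hi = gc3_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise InfeasibleTargetError(f"gc3_range {gc3_range} outside [0, 1]")
    rng = np.random.default_rng(seed)
    k_codons = np.array(code.families[_PANEL_LOW_GC12_AA], dtype="<U3")  # AAA, AAG
    a_codons = np.array(code.families[_PANEL_HIGH_GC12_AA], dtype="<U3")  # GCN
    k_gc = np.array([c[2] in "GC" for c in k_codons])
    a_gc = np.array([c[2] in "GC" for c in a_codons])

    seqs: list[CodingSequence] = []
    truth: list[dict] = []
    for i in range(n):
        gc3 = rng.uniform(lo, hi)
        gc12 = intercept + slope * gc3 + rng.normal(0.0, noise_sd)
        if not 0.0 < gc12 < 1.0:
            raise InfeasibleTargetError(
                f"target gc12 {gc12:.3f} outside (0, 1); adjust line or noise"
            )
        is_ala = rng.random(n_codons) < gc12
        use_gc = rng.random(n_codons) < gc3
        codons = np.empty(n_codons, dtype="<U3")
        for mask, fam_codons, fam_gc in (
            (is_ala, a_codons, a_gc),
            (~is_ala, k_codons, k_gc),
        ):
            gc_pool, at_pool = fam_codons[fam_gc], fam_codons[~fam_gc]
            sel_gc = mask & use_gc
            sel_at = mask & ~use_gc
            codons[sel_gc] = gc_pool[rng.integers(0, len(gc_pool), sel_gc.sum())]
            codons[sel_at] = at_pool[rng.integers(0, len(at_pool), sel_at.sum())]
        seqs.append(CodingSequence(f"panel_{i:04d}", "".join(codons)))
        truth.append({"id": f"panel_{i:04d}", "true_gc3": gc3, "true_gc12": gc12})
    return seqs, truth
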