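"""Effective number of codons, the expected-ENC curve and neutrality regression.

ENC follows Wright: per family, S = sum((n_i/n)^2) and F = (n*S - 1)/(n - 1);
ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk averaged over the computable
families of each degeneracy class. Values are capped at 61.

Neutrality analysis regresses GC12 on GC3s by ordinary least squares; the
slope x100 is read as the percentage of codon-usage variation attributable
to mutation pressure, the remainder to selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .composition import composition_summary
from .genetics import (
    STANDARD_CODE,
    CodingSequence,
    CodonCountTable,
    CubkitError,
    GeneticCode,
    count_codons,
)

ENC_MAX = 61.0
ENC_BIAS_CUTOFF = 35.0  # "significantly high bias" reporting flag


class IncomputableEncError(CubkitError):
    pass


class NeutralityFitError(CubkitError):
    pass


def _family_F(fam_counts: Sequence[int]) -> float | None:
    """Wright's codon-homozygosity F for one family; None when n < 2."""
    n = sum(fam_counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in fam_counts)
    return (n * s - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Effective number of codons of a count table, capped at 61.

    Families with fewer than two codons observed are left out of their
    degeneracy-class average. A missing 3-fold class falls back to the mean
    of the 2- and 4-fold averages (Wright's convention); any other missing
    class makes ENC incomputable.
    """
    class_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in code.families.items():
        f = _family_F([counts.counts.get(c, 0) for c in codons])
        if f is not None:
            class_F[len(codons)].append(f)

    mean_F: dict[int, float] = {}
    for k, fs in class_F.items():
        if fs:
            mean_F[k] = sum(fs) / len(fs)
    # Wright's fallback: a missing (or zero, e.g. a perfectly even Ile
    # family) 3-fold average is imputed from the 2- and 4-fold averages.
    if mean_F.get(3, 0.0) == 0.0 and 2 in mean_F and 4 in mean_F:
        mean_F[3] = (mean_F[2] + mean_F[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if k not in mean_F]
    if missing:
        raise IncomputableEncError(
            f"no computable family in degeneracy class(es) {missing}"
        )
    for k, f in mean_F.items():
        if f <= 0:
            raise IncomputableEncError(
                f"mean F for {k}-fold class is {f:.4g}; ENC undefined"
            )
    value = (
        2.0 + 9.0 / mean_F[2] + 1.0 / mean_F[3] + 5.0 / mean_F[4] + 3.0 / mean_F[6]
    )
    return min(value, ENC_MAX)


def enc_expected(s: float) -> float:
    """Wright's standard ENC-vs-GC3s curve: 2 + s + 29/(s^2 + (1-s)^2)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class EncRecord:
    id: str
    enc: float
    gc3s: float
    gc12: float
    enc_expected: float
    below_curve: bool
    high_bias: bool  # enc < 35

    def as_dict(self) -> dict:
        return asdict(self)


def enc_record(
    seq: CodingSequence, code: GeneticCode = STANDARD_CODE
) -> EncRecord:
    comp = composition_summary(seq, code)
    value = enc(count_codons(seq, code), code)
    expected = enc_expected(comp.GC3s)
    return EncRecord(
        id=seq.id,
        enc=value,
        gc3s=comp.GC3s,
        gc12=comp.GC12,
        enc_expected=expected,
        below_curve=value < expected,
        high_bias=value < ENC_BIAS_CUTOFF,
    )


def enc_plot_data(records: Iterable[EncRecord]) -> list[dict]:
    return [r.as_dict() for r in records]


@dataclass
class NeutralityFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int
    pct_mutation: float
    pct_selection: float
    _x: np.ndarray = None
    _y: np.ndarray = None

    def slope_ci95(self) -> tuple[float, float]:
        t = stats.t.ppf(0.975, self.n - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)

    def confidence_band(self, xq) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence interval of the mean response at the given GC3s."""
        xq = np.asarray(xq, dtype=float)
        yhat = self.intercept + self.slope * self._x
        mse = np.sum((self._y - yhat) ** 2) / (self.n - 2)
        sxx = np.sum((self._x - self._x.mean()) ** 2)
        se = np.sqrt(mse * (1.0 / self.n + (xq - self._x.mean()) ** 2 / sxx))
        t = stats.t.ppf(0.975, self.n - 2)
        yq = self.intercept + self.slope * xq
        return yq - t * se, yq + t * se

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("_x"), d.pop("_y")
        return d


def neutrality_fit(points: Sequence[tuple[float, float]]) -> NeutralityFit:
    """OLS of GC12 on GC3s over (gc3s, gc12) pairs."""
    if len(points) < 3:
        raise NeutralityFitError("need at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise NeutralityFitError("GC3s has zero variance; slope undefined")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue ** 2,
        p_value=res.pvalue,
        stderr=res.stderr,
        n=len(points),
        pct_mutation=100.0 * res.slope,
        pct_selection=100.0 * (1.0 - res.slope),
        _x=x,
        _y=y,
    )


def neutrality_points(
    seqs: Iterable[CodingSequence], code: GeneticCode = STANDARD_CODE
) -> list[tuple[float, float]]:
    out = []
    for seq in seqs:
        comp = composition_summary(seq, code)
        out.append((comp.GC3s, comp.GC12))
    return out
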