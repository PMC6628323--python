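"""Core sequence objects: the genetic code, validated coding sequences and codon counts.

Everything downstream (composition, RSCU, ENC, CAI, ...) is defined over the
59 sense codons of the standard nuclear code: Met (ATG), Trp (TGG) and the
three stop codons are excluded from all synonymous-usage statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SINGLE_CODON_AAS = frozenset({"M", "W"})  # ATG, TGG


class CubkitError(Exception):
    """Base class for all toolkit errors."""


class CdsValidationError(CubkitError):
    """A coding sequence violates frame or stop-codon constraints."""

    def __init__(self, record_id: str, reason: str):
        self.record_id = record_id
        self.reason = reason
        super().__init__(f"{record_id}: {reason}")


class EmptyInputError(CubkitError):
    pass


def _build_standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


class GeneticCode:
    """Standard nuclear genetic code with its synonymous-family structure.

    Attributes
    ----------
    codon_to_aa : mapping of all 64 codons to one-letter amino acids ('*' = stop).
    families : mapping amino acid -> tuple of synonymous codons, restricted to
        the 18 families with two or more codons (Met, Trp and stops excluded).
    sense_codons : the 59 codons participating in synonymous-usage statistics.
    """

    def __init__(self) -> None:
        self.codon_to_aa: dict[str, str] = _build_standard_code()
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa == "*" or aa in SINGLE_CODON_AAS:
                continue
            fams.setdefault(aa, []).append(codon)
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(codons)) for aa, codons in sorted(fams.items())
        }
        self.sense_codons: tuple[str, ...] = tuple(
            c for codons in self.families.values() for c in codons
        )
        self.codon_to_family: dict[str, str] = {
            c: aa for aa, codons in self.families.items() for c in codons
        }

    def family_size(self, aa: str) -> int:
        return len(self.families[aa])

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Group family amino acids by degeneracy (2-, 3-, 4- and 6-fold)."""
        out: dict[int, list[str]] = {}
        for aa, codons in self.families.items():
            out.setdefault(len(codons), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in sorted(out.items())}

    def is_sense(self, codon: str) -> bool:
        return codon in self.codon_to_family


#: Module-level singleton; the code is fixed, so sharing it is safe.
STANDARD_CODE = GeneticCode()


def _is_clean_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame CDS.

    ``nucleotides`` is uppercase DNA; length is a positive multiple of three
    and no internal stop codon occurs (a terminal stop is permitted, matching
    complete ORFs). Codons containing ambiguity symbols are retained in the
    sequence but skipped by :func:`count_codons`.
    """

    id: str
    nucleotides: str

    def __post_init__(self) -> None:
        seq = self.nucleotides
        if not seq:
            raise CdsValidationError(self.id, "empty sequence")
        if len(seq) % 3 != 0:
            raise CdsValidationError(
                self.id, f"length {len(seq)} is not a multiple of 3"
            )
        for idx, codon in enumerate(self.codons[:-1]):
            if codon in STOP_CODONS:
                raise CdsValidationError(
                    self.id, f"internal stop codon {codon} at codon {idx + 1}"
                )

    @property
    def codons(self) -> list[str]:
        seq = self.nucleotides
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    @classmethod
    def from_raw(
        cls, record_id: str, raw: str, frame_policy: str = "strict"
    ) -> "CodingSequence":
        """Normalize (upper-case, U->T) and validate a raw sequence string.

        frame_policy 'trim_trailing' drops 1-2 trailing bases instead of
        erroring on out-of-frame input.
        """
        seq = raw.strip().upper().replace("U", "T")
        if frame_policy == "trim_trailing" and len(seq) % 3 != 0:
            seq = seq[: len(seq) - len(seq) % 3]
        elif frame_policy not in ("strict", "trim_trailing"):
            raise ValueError(f"unknown frame_policy {frame_policy!r}")
        return cls(record_id, seq)


@dataclass
class CodonCountTable:
    """Observed codon counts plus the bookkeeping every statistic needs."""

    counts: Counter = field(default_factory=Counter)
    n_excluded: int = 0  # codons skipped for containing ambiguity symbols
    code: GeneticCode = field(default=STANDARD_CODE, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in self.code.families[aa]}

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in self.code.families[aa])

    def synonymous_total(self) -> int:
        return sum(
            n for codon, n in self.counts.items() if self.code.is_sense(codon)
        )

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            counts=self.counts + other.counts,
            n_excluded=self.n_excluded + other.n_excluded,
            code=self.code,
        )


def count_codons(seq: CodingSequence, code: GeneticCode = STANDARD_CODE) -> CodonCountTable:
    """Tally codons of a CDS; ambiguous codons are excluded and tallied apart."""
    counts: Counter = Counter()
    n_excluded = 0
    for codon in seq.codons:
        if _is_clean_codon(codon):
            counts[codon] += 1
        else:
            n_excluded += 1
    return CodonCountTable(counts=counts, n_excluded=n_excluded, code=code)


def pool_counts(tables: Iterable[CodonCountTable]) -> CodonCountTable:
    tables = list(tables)
    if not tables:
        raise EmptyInputError("no count tables to pool")
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled + t
    return pooled


def read_fasta(
    path: str | Path, frame_policy: str = "strict"
) -> list[CodingSequence]:
    """Read and validate all CDS records of a FASTA file.

    Raises :class:`CdsValidationError` on the first invalid record (strict
    contract); use :func:`validate_fasta` to get a per-record report instead.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return [
        CodingSequence.from_raw(rec.id, str(rec.seq), frame_policy)
        for rec in records
    ]


def validate_fasta(
    path: str | Path, frame_policy: str = "strict"
) -> tuple[list[CodingSequence], list[dict]]:
    """Like :func:`read_fasta` but collects failures instead of raising.

    Returns (valid sequences, per-record report rows). Report rows carry
    id, length, n_codons, status and reason, so failures are visible rather
    than silently dropped.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    valid: list[CodingSequence] = []
    report: list[dict] = []
    for rec in records:
        row = {"id": rec.id, "length": len(rec.seq), "n_codons": len(rec.seq) // 3}
        try:
            cds = CodingSequence.from_raw(rec.id, str(rec.seq), frame_policy)
        except CdsValidationError as err:
            row.update(status="invalid", reason=err.reason)
        else:
            valid.append(cds)
            row.update(
                status="ok", reason="", length=len(cds.nucleotides),
                n_codons=cds.n_codons,
            )
        report.append(row)
    return valid, report


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.nucleotides), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def iter_codons(nucleotides: str) -> Iterator[str]:
    for i in range(0, len(nucleotides) - len(nucleotides) % 3, 3):
        yield nucleotides[i : i + 3]
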