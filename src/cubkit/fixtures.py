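"""Bundled RSCU reference tables.

Four 59-codon RSCU profiles ship with the package: two torque teno sus
virus genus-level profiles (``ttsuv1``, ``ttsuv2``) and two host tables
(``sus_scrofa``, ``sus_scrofa_domestica``). They are stored as plain TSV
(aa, codon, rscu) under ``cubkit/data`` and load as external-table profiles.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .genetics import STANDARD_CODE, CubkitError, GeneticCode
from .rscu import RscuProfile

FIXTURE_NAMES = ("ttsuv1", "ttsuv2", "sus_scrofa", "sus_scrofa_domestica")


def _data_path(name: str) -> Path:
    return resources.files("cubkit").joinpath("data", f"{name}.tsv")


def load_rscu_table(
    path, code: GeneticCode = STANDARD_CODE
) -> RscuProfile:
    """Load a 59-codon RSCU profile from a TSV with columns codon and rscu
    (an optional aa column is ignored; U and T alphabets both accepted)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "codon" not in reader.fieldnames:
            raise CubkitError(f"{path}: expected TSV with 'codon' and 'rscu' columns")
        for row in reader:
            codon = row["codon"].strip().upper().replace("U", "T")
            values[codon] = float(row["rscu"])
    missing = [c for c in code.sense_codons if c not in values]
    if missing:
        raise CubkitError(
            f"{path}: missing {len(missing)} sense codons (e.g. {missing[:3]})"
        )
    return RscuProfile(
        values={c: values[c] for c in code.sense_codons},
        source="external_table",
        code=code,
    )


def load_fixture(name: str, code: GeneticCode = STANDARD_CODE) -> RscuProfile:
    if name not in FIXTURE_NAMES:
        raise CubkitError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    with resources.as_file(_data_path(name)) as path:
        return load_rscu_table(path, code)
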