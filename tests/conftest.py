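import numpy as np
import pytest

from cubkit import (
    STANDARD_CODE,
    CodingSequence,
    GeneratorSpec,
    generate,
    load_fixture,
    write_fasta,
)


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def ttsuv1():
    return load_fixture("ttsuv1")


@pytest.fixture(scope="session")
def ttsuv2():
    return load_fixture("ttsuv2")


@pytest.fixture(scope="session")
def sus_scrofa():
    return load_fixture("sus_scrofa")


@pytest.fixture(scope="session")
def sus_scrofa_domestica():
    return load_fixture("sus_scrofa_domestica")


@pytest.fixture
def fasta_factory(tmp_path):
    """Write (id, sequence) pairs to a temp FASTA and return the path."""

    def _make(records, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _make


@pytest.fixture(scope="session")
def small_synthetic_seqs():
    """Ten modest unbiased sequences shared across CLI/report tests."""
    seqs, _ = generate(GeneratorSpec(n_sequences=10, n_codons=300, seed=42))
    return seqs


@pytest.fixture
def small_synthetic_fasta(small_synthetic_seqs, tmp_path):
    path = tmp_path / "synthetic.fasta"
    write_fasta(small_synthetic_seqs, path)
    return path


def random_count_table(rng, code=STANDARD_CODE, max_per_family=50):
    """Random codon counts over all 18 families, each family observed."""
    from collections import Counter

    from cubkit import CodonCountTable

    counts = Counter()
    for aa, codons in code.families.items():
        n = rng.integers(2, max_per_family + 1)
        split = rng.multinomial(n, np.ones(len(codons)) / len(codons))
        for c, k in zip(codons, split):
            if k:
                counts[c] += int(k)
    return CodonCountTable(counts=counts, code=code)
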