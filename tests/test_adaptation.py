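import math
from collections import Counter

import numpy as np
import pytest

from cubkit import (
    CodingSequence,
    CodonCountTable,
    GeneratorSpec,
    HostReference,
    cai,
    count_codons,
    generate,
    load_host_reference,
    rcdi,
    rscu_from_counts,
    sid,
)
from cubkit.adaptation import (
    IncompleteReferenceError,
    parse_kazusa,
    reference_from_usage,
)
from cubkit.genetics import STANDARD_CODE, CubkitError
from cubkit.rscu import RscuProfile


def uniform_reference(name="uniform") -> HostReference:
    values = {c: 1.0 for c in STANDARD_CODE.sense_codons}
    return HostReference(
        name=name,
        rscu=RscuProfile(values=values, source="external_table"),
    )


def counts_of(codon_map) -> CodonCountTable:
    return CodonCountTable(counts=Counter(codon_map))


class TestHostReference:
    def test_sus_scrofa_glu_weights(self):
        host = load_host_reference("sus_scrofa")
        # Glu RSCU 0.72 / 1.28 -> w(GAG)=1, w(GAA)=0.72/1.28
        assert host.w["GAG"] == pytest.approx(1.0)
        assert host.w["GAA"] == pytest.approx(0.72 / 1.28)
        assert host.w["GAA"] == pytest.approx(0.5625)

    def test_family_max_w_is_one(self):
        host = load_host_reference("sus_scrofa_domestica")
        for aa, codons in STANDARD_CODE.families.items():
            assert max(host.w[c] for c in codons) == pytest.approx(1.0)

    def test_family_freq_sums_to_one(self):
        host = load_host_reference("sus_scrofa")
        for aa, codons in STANDARD_CODE.families.items():
            assert sum(host.family_freq[c] for c in codons) == pytest.approx(1.0)

    def test_uniform_reference_all_w_one(self):
        host = uniform_reference()
        assert all(w == pytest.approx(1.0) for w in host.w.values())

    def test_zero_usage_floored_not_infinite(self, caplog):
        values = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        values["GAA"], values["GAG"] = 0.0, 2.0
        host = HostReference(
            name="zeroed",
            rscu=RscuProfile(values=values, source="external_table"),
        )
        assert host.w["GAA"] > 0.0
        c = cai(counts_of({"GAA": 3}), host)
        assert math.isfinite(c) and c > 0.0


class TestKazusa:
    TEXT = None  # built lazily from the fixture so all 59 codons are covered

    def _make_text(self):
        host = load_host_reference("sus_scrofa")
        fields = []
        for codon in STANDARD_CODE.codon_to_aa:
            # counts proportional to rscu for sense codons, 1.0 elsewhere
            val = host.rscu.values.get(codon, 1.0) * 1000
            fields.append(f"{codon.replace('T', 'U')} {val / 1000:.1f}({int(val)})")
        lines = [" ".join(fields[i : i + 4]) for i in range(0, len(fields), 4)]
        return "\n".join(lines)

    def test_round_trip(self):
        text = self._make_text()
        usage1 = parse_kazusa(text)
        host = reference_from_usage("rt", usage1)
        # re-emit from parsed counts and re-parse
        text2 = " ".join(
            f"{c.replace('T', 'U')} {u / 1000:.3f}({int(u)})" for c, u in usage1.items()
        )
        usage2 = parse_kazusa(text2)
        assert usage1 == usage2
        host2 = reference_from_usage("rt2", usage2)
        for c in STANDARD_CODE.sense_codons:
            assert host.w[c] == pytest.approx(host2.w[c])

    def test_missing_codons_rejected(self):
        with pytest.raises(IncompleteReferenceError):
            reference_from_usage("bad", {"GAA": 1.0, "GAG": 2.0})

    def test_unparseable_rejected(self):
        with pytest.raises(IncompleteReferenceError):
            parse_kazusa("this is not a codon usage table")


class TestCai:
    def test_host_optimal_gene_is_one(self):
        host = load_host_reference("sus_scrofa")
        optimal = {host.rscu.preferred(aa): 5 for aa in STANDARD_CODE.families}
        assert cai(counts_of(optimal), host) == pytest.approx(1.0)

    def test_glu_closed_form(self):
        host = load_host_reference("sus_scrofa")
        value = cai(counts_of({"GAA": 1, "GAG": 1}), host)
        assert value == pytest.approx(math.exp((math.log(0.5625) + 0.0) / 2))
        assert value == pytest.approx(0.75)

    def test_uniform_host_gives_one(self):
        host = uniform_reference()
        assert cai(counts_of({"GAA": 3, "GGG": 2, "CTA": 7}), host) == pytest.approx(1.0)

    def test_scale_invariance(self):
        host = load_host_reference("sus_scrofa")
        base = {"GAA": 2, "AAA": 3, "GGC": 1}
        a = cai(counts_of(base), host)
        b = cai(counts_of({c: 13 * n for c, n in base.items()}), host)
        assert a == pytest.approx(b)

    def test_in_unit_interval(self):
        host = load_host_reference("sus_scrofa_domestica")
        rng = np.random.default_rng(21)
        seqs, _ = generate(GeneratorSpec(n_sequences=5, n_codons=500, seed=21))
        for s in seqs:
            assert 0.0 < cai(count_codons(s), host) <= 1.0

    def test_no_synonymous_codons_errors(self):
        with pytest.raises(CubkitError):
            cai(counts_of({"ATG": 3}), uniform_reference())


class TestRcdi:
    def test_identical_usage_is_one(self):
        host = load_host_reference("sus_scrofa")
        # gene whose within-family frequencies equal the host's: counts
        # proportional to the host RSCU values (scaled to integers)
        counts = {
            c: round(host.rscu.values[c] * 100) for c in STANDARD_CODE.sense_codons
        }
        assert rcdi(counts_of(counts), host) == pytest.approx(1.0, abs=5e-3)

    def test_single_codon_closed_form(self):
        host = load_host_reference("sus_scrofa")
        # virus uses GAA only: CiF_virus=1, host CiF = 0.72/2 = 0.36
        assert rcdi(counts_of({"GAA": 10}), host) == pytest.approx(1 / 0.36, rel=1e-9)

    def test_sampled_from_host_frequencies_near_one(self):
        host = load_host_reference("sus_scrofa")
        weights = {
            aa: {c: host.family_freq[c] for c in codons}
            for aa, codons in STANDARD_CODE.families.items()
        }
        seqs, _ = generate(
            GeneratorSpec(
                n_sequences=1, n_codons=5000, family_codon_weights=weights, seed=8
            )
        )
        assert rcdi(count_codons(seqs[0]), host) == pytest.approx(1.0, abs=0.05)

    def test_monotone_deoptimization(self):
        # starting from host-matched usage, progressively swapping the
        # host-optimal codon for a host-rare synonym never raises CAI and
        # never lowers RCDI (RCDI is minimized at host-matched usage)
        host = load_host_reference("sus_scrofa")
        # Glu host within-family frequencies: GAA 0.36, GAG 0.64
        assert host.family_freq["GAA"] == pytest.approx(0.36)
        prev = {"GAA": 36, "GAG": 64}
        for k in range(1, 33):
            worse = {"GAA": 36 + 2 * k, "GAG": 64 - 2 * k}
            assert cai(counts_of(worse), host) <= cai(counts_of(prev), host) + 1e-12
            assert rcdi(counts_of(worse), host) >= rcdi(counts_of(prev), host) - 1e-12
            prev = worse


class TestSid:
    def test_identical_profiles_zero(self, ttsuv1):
        assert sid(ttsuv1, ttsuv1) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_half(self):
        a = {c: 0.0 for c in STANDARD_CODE.sense_codons}
        b = dict(a)
        a["GAA"], b["GAG"] = 2.0, 2.0
        pa = RscuProfile(values=a, source="external_table")
        pb = RscuProfile(values=b, source="external_table")
        assert sid(pa, pb) == pytest.approx(0.5)

    def test_symmetry(self, ttsuv1, sus_scrofa):
        assert sid(ttsuv1, sus_scrofa) == pytest.approx(sid(sus_scrofa, ttsuv1))

    def test_bounded_for_nonnegative_profiles(self, ttsuv2, sus_scrofa_domestica):
        d = sid(ttsuv2, sus_scrofa_domestica)
        assert 0.0 <= d <= 0.5

    def test_zero_norm_errors(self):
        zeros = RscuProfile(
            values={c: 0.0 for c in STANDARD_CODE.sense_codons},
            source="external_table",
        )
        with pytest.raises(CubkitError):
            sid(zeros, zeros)

    def test_paper_table_values(self, ttsuv1, ttsuv2, sus_scrofa, sus_scrofa_domestica):
        assert sid(ttsuv1, sus_scrofa) == pytest.approx(0.094, abs=0.0015)
        assert sid(ttsuv2, sus_scrofa) == pytest.approx(0.149, abs=0.0015)
        assert sid(ttsuv1, sus_scrofa_domestica) == pytest.approx(0.068, abs=0.0015)
        assert sid(ttsuv2, sus_scrofa_domestica) == pytest.approx(0.132, abs=0.0015)
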