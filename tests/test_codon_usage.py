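import numpy as np
import pytest

from mitocomp import genetic_code as gc
from mitocomp.codon_usage import (CodonUsageTable, InternalStopError,
                                  at_ending_fraction, cbi, count_codons, enc,
                                  gc3, linear_fit, modal_codons, rscu,
                                  unused_codons)


def table_from_counts(counts):
    return CodonUsageTable(transl_table=5, counts=dict(counts))


def uniform_table(per_codon=10):
    return table_from_counts({c: per_codon for c in gc.sense_codons(5)})


def maximally_biased_table(per_family=5):
    counts = {}
    for aa, codons in gc.synonymous_families(5).items():
        counts[codons[0]] = per_family
    return table_from_counts(counts)


class TestCountCodons:
    def test_stop_excluded(self):
        t = count_codons(["ATGTTTTAA"])
        assert t.counts == {"ATG": 1, "TTT": 1}

    def test_truncated_terminal_stop_dropped(self):
        t = count_codons(["ATGTTTT"])
        assert t.counts == {"ATG": 1, "TTT": 1}
        t = count_codons(["ATGTTTTA"])
        assert t.counts == {"ATG": 1, "TTT": 1}

    def test_internal_stop_names_gene_and_position(self):
        with pytest.raises(InternalStopError, match="cox1.*codon 2"):
            count_codons(["ATGTAATTTTAA"], names=["cox1"])

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            count_codons(["ATGTTTTC"])

    def test_ambiguous_codons_dropped(self):
        t = count_codons(["ATGANTTTTTAA"])
        assert t.dropped == 1
        assert t.counts == {"ATG": 1, "TTT": 1}

    def test_total_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        sense = gc.sense_codons(5)
        cds_set = []
        for _ in range(10):
            n = int(rng.integers(5, 40))
            cds_set.append("".join(rng.choice(sense, n)) + "TAA")
        t = count_codons(cds_set)
        assert t.total == sum((len(c) // 3) - 1 for c in cds_set)


class TestRscu:
    def test_uniform_usage_gives_one(self):
        rel = rscu(uniform_table())
        assert all(v == pytest.approx(1.0) for v in rel.values())

    def test_single_codon_in_fourfold_family(self):
        rel = rscu(table_from_counts({"GTT": 8}))
        assert rel["GTT"] == pytest.approx(4.0)
        assert rel["GTA"] == 0.0

    def test_family_sums_equal_family_size(self):
        rng = np.random.default_rng(0)
        counts = {c: int(rng.integers(0, 30)) for c in gc.sense_codons(5)}
        t = table_from_counts(counts)
        rel = rscu(t)
        for aa, codons in t.families.items():
            if sum(counts[c] for c in codons) == 0:
                assert all(rel[c] is None for c in codons)
            else:
                assert sum(rel[c] for c in codons) == pytest.approx(len(codons))


class TestEnc:
    def test_uniform_usage_is_62(self):
        assert enc(uniform_table()) == pytest.approx(62.0)

    def test_one_codon_per_family_is_20(self):
        assert enc(maximally_biased_table()) == pytest.approx(20.0)

    def test_bounds_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            counts = {c: int(rng.integers(2, 50)) for c in gc.sense_codons(5)}
            value = enc(table_from_counts(counts))
            assert 20.0 <= value <= 62.0

    def test_monotone_under_concentration(self):
        """ENC decreases as usage concentrates on one codon per family."""
        fams = gc.synonymous_families(5)
        values = []
        total = 600
        for lam in np.linspace(0.0, 1.0, 6):
            counts = {}
            for aa, codons in fams.items():
                k = len(codons)
                base = total // k
                for i, c in enumerate(codons):
                    share = (1 - lam) * base + (lam * total if i == 0 else 0)
                    counts[c] = int(round(share))
            values.append(enc(table_from_counts(counts)))
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
        assert values[0] > 55 and values[-1] < 25

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            enc(table_from_counts({}))


class TestCbi:
    def test_only_preferred_codons_gives_one(self):
        assert cbi(maximally_biased_table()) == pytest.approx(1.0)

    def test_uniform_usage_gives_zero(self):
        assert cbi(uniform_table()) == pytest.approx(0.0)

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            counts = {c: int(rng.integers(0, 40)) for c in gc.sense_codons(5)}
            if sum(counts.values()) == 0:
                continue
            value = cbi(table_from_counts(counts))
            assert value <= 1.0 + 1e-12

    def test_explicit_preferred_set(self):
        t = uniform_table()
        preferred = modal_codons(t)
        assert cbi(t, preferred) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cbi(t, {"F": "GGG"})  # GGG is not a Phe codon

    def test_empty_table_is_missing(self):
        assert cbi(table_from_counts({})) is None


class TestAtEnding:
    def test_all_a_ending(self):
        t = table_from_counts({"TTA": 5, "GGA": 3})
        assert at_ending_fraction(t) == 1.0

    def test_complement_of_gc3(self):
        rng = np.random.default_rng(6)
        counts = {c: int(rng.integers(0, 25)) for c in gc.sense_codons(5)}
        t = table_from_counts(counts)
        assert at_ending_fraction(t) + gc3(t) == pytest.approx(1.0)


class TestUnused:
    def test_zero_count_scan(self):
        counts = {c: 1 for c in gc.sense_codons(5)}
        for dropped in ("CTC", "GCG", "GGC"):
            del counts[dropped]
        assert unused_codons(table_from_counts(counts)) == {"CTC", "GCG", "GGC"}


class TestLinearFit:
    def test_collinear_points(self):
        slope, intercept, r2 = linear_fit([1, 2, 3, 4], [3, 5, 7, 9])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_anticorrelated_line(self):
        slope, _, r2 = linear_fit([0, 1, 2], [4, 2, 0])
        assert slope < 0
        assert r2 == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            linear_fit([1, 2], [1, 2])
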