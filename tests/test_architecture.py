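import numpy as np
import pytest

from mitocomp.architecture import (classify_terminal_codons, find_gene_overlaps,
                                   find_noncoding_regions, shared_overlap_motif,
                                   total_noncoding_length)


def brute_force_overlaps(features, L):
    """Independent oracle: adjacent-pair circular interval intersections."""
    def interval(f):
        return (f.start, f.end + L) if f.wraps else (f.start, f.end)

    feats = sorted(features, key=lambda f: (f.start, f.end))
    out = []
    n = len(feats)
    for i in range(n):
        a, b = feats[i], feats[(i + 1) % n]
        a_s, a_e = interval(a)
        b_s, b_e = interval(b)
        if i + 1 == n:
            b_s, b_e = b_s + L, b_e + L
        ov = min(a_e, b_e) - max(a_s, b_s)
        if ov >= 1:
            out.append((a.name, b.name, ov))
    return out


class TestGeneOverlaps:
    def test_abutting_features_do_not_overlap(self, toy_genome_factory,
                                              gene_factory):
        g = toy_genome_factory("A" * 20, [gene_factory("cox1", 0, 10),
                                          gene_factory("cox2", 10, 20)])
        assert find_gene_overlaps(g) == []

    def test_matches_interval_oracle_on_random_genomes(self, toy_genome_factory,
                                                       gene_factory):
        rng = np.random.default_rng(11)
        names = ["cox1", "cox2", "cox3", "nad1", "nad2", "cytb"]
        for _ in range(30):
            L = int(rng.integers(120, 300))
            starts = sorted(rng.choice(L - 20, size=len(names), replace=False))
            feats = []
            for name, s in zip(names, starts):
                span = int(rng.integers(10, 40))
                e = min(int(s) + span, L)
                feats.append(gene_factory(name, int(s), e))
            g = toy_genome_factory("A" * L, feats)
            got = [(o.gene_a, o.gene_b, o.length) for o in find_gene_overlaps(g)]
            assert got == brute_force_overlaps(feats, L)

    def test_planted_motif_overlaps(self, default_genome):
        genome, truth = default_genome
        overlaps = {(o.gene_a, o.gene_b): o for o in find_gene_overlaps(genome)}
        for (a, b), (start, end, motif) in truth.overlaps.items():
            rec = overlaps[(a, b)]
            assert rec.length == len(motif) == 7
            assert rec.start == start and rec.end == end
        assert overlaps[("atp8", "atp6")].sequence == "ATGATAA"


class TestSharedOverlapMotif:
    def test_identical_across_genomes(self, genome_batch):
        genomes = [g for g, _ in genome_batch]
        assert shared_overlap_motif(genomes, ("atp8", "atp6")) == "ATGATAA"
        # N-strand pair is reported on the genes' coding strand
        assert shared_overlap_motif(genomes, ("nad4", "nad4L")) == "ATGATAA"

    def test_differing_sequences_reported_per_genome(self, toy_genome_factory,
                                                     gene_factory):
        g1 = toy_genome_factory("AAATTTCCC" + "G" * 11,
                                [gene_factory("cox1", 0, 6),
                                 gene_factory("cox2", 3, 9)], "g1")
        g2 = toy_genome_factory("AAAGGGCCC" + "G" * 11,
                                [gene_factory("cox1", 0, 6),
                                 gene_factory("cox2", 3, 9)], "g2")
        got = shared_overlap_motif([g1, g2], ("cox1", "cox2"))
        assert got == {"g1": "TTT", "g2": "GGG"}

    def test_absent_pair_returns_none(self, toy_genome_factory, gene_factory):
        g = toy_genome_factory("A" * 30, [gene_factory("cox1", 0, 10),
                                          gene_factory("cox2", 15, 25)])
        assert shared_overlap_motif([g], ("cox1", "cox2")) is None


class TestNoncodingRegions:
    def test_fully_tiled_genome_has_no_nc(self, toy_genome_factory,
                                          gene_factory):
        g = toy_genome_factory("A" * 30, [gene_factory("cox1", 0, 15),
                                          gene_factory("cox2", 15, 30)])
        assert find_noncoding_regions(g) == []

    def test_single_gap_is_large_flagged(self, toy_genome_factory,
                                         gene_factory):
        g = toy_genome_factory("A" * 400, [gene_factory("cox1", 0, 100),
                                           gene_factory("cox2", 350, 400)])
        regions = find_noncoding_regions(g, min_large=100)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.length, r.is_large) == (100, 350, 250, True)
        assert (r.flank_a, r.flank_b) == ("cox1", "cox2")

    def test_matches_set_complement_oracle(self, toy_genome_factory,
                                           gene_factory):
        rng = np.random.default_rng(5)
        for _ in range(20):
            L = int(rng.integers(100, 250))
            feats = []
            pos = int(rng.integers(0, 10))
            names = iter(["cox1", "cox2", "cox3", "nad1", "nad2"])
            while pos + 20 < L:
                span = int(rng.integers(10, 30))
                try:
                    feats.append(gene_factory(next(names), pos,
                                              min(pos + span, L)))
                except StopIteration:
                    break
                pos += span + int(rng.integers(0, 25))
            g = toy_genome_factory("A" * L, feats)
            covered = np.zeros(L, dtype=bool)
            for f in feats:
                covered[f.start:f.end] = True
            assert sum(r.length for r in find_noncoding_regions(g)) == \
                int((~covered).sum())

    def test_cr_labelled_between_rrns_and_trni(self, default_genome):
        genome, truth = default_genome
        regions = find_noncoding_regions(genome)
        cr = [r for r in regions if r.label == "CR"]
        assert len(cr) == 1
        assert (cr[0].start, cr[0].end) == truth.cr_span
        assert total_noncoding_length(genome) == sum(r.length for r in regions)

    def test_featureless_genome_raises(self, toy_genome_factory):
        g = toy_genome_factory("A" * 30, [])
        with pytest.raises(ValueError):
            find_noncoding_regions(g)


class TestTerminalCodons:
    def test_full_stop_and_start(self, toy_genome_factory, gene_factory):
        g = toy_genome_factory("ATGAAATTTTAA" + "C" * 8,
                               [gene_factory("cox1", 0, 12)])
        (rec,) = classify_terminal_codons(g)
        assert (rec.start_codon, rec.stop_codon, rec.truncated) == \
            ("ATG", "TAA", False)
        assert rec.anomaly is None

    def test_truncated_stop_requires_abutting_trna(self, toy_genome_factory,
                                                   gene_factory):
        seq = "ATGAAATTTT" + "A" * 60 + "C" * 10
        with_trna = toy_genome_factory(seq, [
            gene_factory("cox1", 0, 10),
            gene_factory("trnK", 10, 70, kind="tRNA")])
        (rec,) = classify_terminal_codons(with_trna)
        assert (rec.stop_codon, rec.truncated, rec.anomaly) == ("T", True, None)
        gapped = toy_genome_factory(seq, [
            gene_factory("cox1", 0, 10),
            gene_factory("trnK", 12, 70, kind="tRNA")])
        (rec,) = classify_terminal_codons(gapped)
        assert rec.truncated is False
        assert rec.anomaly is not None

    def test_short_cds_raises(self, toy_genome_factory, gene_factory):
        g = toy_genome_factory("ATGCA" + "A" * 10,
                               [gene_factory("cox1", 0, 5)])
        with pytest.raises(ValueError):
            classify_terminal_codons(g)

    def test_synthetic_genome_truncated_stops(self, default_genome):
        genome, _ = default_genome
        records = {r.gene: r for r in classify_terminal_codons(genome)}
        assert records["cox1"].start_codon == "TTG"
        assert (records["cox2"].stop_codon, records["cox2"].truncated) == \
            ("T", True)
        assert (records["nad5"].stop_codon, records["nad5"].truncated) == \
            ("TA", True)
        assert all(r.anomaly is None for r in records.values())


class TestCircularConservation:
    def test_features_plus_nc_minus_overlaps_equals_length(self, genome_batch):
        """Length bookkeeping closes exactly on the circle."""
        for genome, _ in genome_batch:
            L = len(genome)
            gene_total = sum(f.length(L) for f in genome.genes())
            nc_total = sum(r.length for r in find_noncoding_regions(genome))
            ov_total = sum(o.length for o in find_gene_overlaps(genome))
            assert gene_total + nc_total - ov_total == L
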