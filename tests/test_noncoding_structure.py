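import numpy as np
import pytest

from mitocomp.noncoding_structure import (annotate_control_region,
                                          find_composition_blocks,
                                          find_stem_loops,
                                          find_tandem_repeats)
from mitocomp.synthetic_data import (CRSpec, RepeatSpec, _base_probs,
                                     _build_repeat, _random_seq,
                                     generate_control_region)


class TestTandemRepeats:
    def test_exact_planted_repeat(self):
        # C homopolymer flanks are trivially periodic themselves, but cannot
        # extend the planted array (no boundary base matches)
        seq = "C" * 40 + "GATTACA" * 5 + "C" * 40
        calls = find_tandem_repeats(seq, min_unit=7, max_unit=30,
                                    min_identity=0.9)
        hit = [r for r in calls if r.consensus == "GATTACA"]
        assert len(hit) == 1
        r = hit[0]
        assert r.unit_length == 7
        assert r.copies == pytest.approx(5.0)
        assert r.identity == 1.0
        assert (r.start, r.end) == (40, 75)

    def test_divergent_planted_repeat_recovered(self):
        rng = np.random.default_rng(17)
        rep, unit, copies = _build_repeat(rng, RepeatSpec(100, 4.0, 0.05),
                                          _base_probs(0.7))
        seq = (_random_seq(rng, 120, _base_probs(0.7)) + rep
               + _random_seq(rng, 120, _base_probs(0.7)))
        calls = find_tandem_repeats(seq, min_unit=10, max_unit=150)
        assert any(abs(r.unit_length - 100) <= 2 and abs(r.copies - copies) <= 0.5
                   for r in calls)

    def test_short_sequence_returns_empty(self):
        assert find_tandem_repeats("ACGT", min_unit=10) == []

    def test_no_repeat_in_plain_random_sequence(self):
        rng = np.random.default_rng(23)
        seq = _random_seq(rng, 300, np.array([0.25, 0.25, 0.25, 0.25]))
        calls = find_tandem_repeats(seq, min_unit=15, max_unit=100,
                                    min_identity=0.9)
        assert calls == []


class TestCompositionBlocks:
    def test_planted_blocks_recovered_within_half_window(self):
        for seed in (0, 1, 2, 3, 4):
            cr, blocks, _, _ = generate_control_region(CRSpec(), seed)
            ann = find_composition_blocks(cr)
            for kind, block in (("GA", ann.ga_block), ("C", ann.c_block),
                                ("AT", ann.at_block)):
                ps, pe = blocks[kind]
                assert block is not None, (seed, kind)
                assert abs(block.start - ps) <= 10
                assert abs(block.end - pe) <= 10

    def test_uniform_sequence_has_no_blocks_at_high_thresholds(self):
        rng = np.random.default_rng(8)
        seq = _random_seq(rng, 400, np.array([0.25, 0.25, 0.25, 0.25]))
        ann = find_composition_blocks(seq, ga_threshold=0.8, c_threshold=0.8,
                                      at_threshold=0.8)
        assert ann.ga_block is None
        assert ann.c_block is None
        assert ann.at_block is None

    def test_idempotent_and_flank_invariant(self):
        cr, _, _, _ = generate_control_region(CRSpec(), 3)
        first = find_composition_blocks(cr)
        second = find_composition_blocks(cr)
        assert (first.ga_block, first.c_block, first.at_block) == \
            (second.ga_block, second.c_block, second.at_block)
        pad = "CT" * 20  # neutral: no GA, 50% C, 50% AT
        shifted = find_composition_blocks(pad + cr)
        # block edges blend with the flanking window, so padding reproduces
        # the segmentation to within half a window
        for a, b in ((shifted.ga_block, first.ga_block),
                     (shifted.c_block, first.c_block),
                     (shifted.at_block, first.at_block)):
            assert abs(a.start - (b.start + len(pad))) <= 10
            assert abs(a.end - (b.end + len(pad))) <= 10

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            find_composition_blocks("ACGT")


class TestStemLoops:
    def test_simple_hairpin(self):
        seq = "GGGGG" + "AAAA" + "CCCCC"
        calls = find_stem_loops(seq, min_stem=5, loop_range=(3, 6))
        assert calls
        h = calls[0]
        assert (h.start, h.end, h.stem_len, h.loop_len) == (0, 14, 5, 4)
        assert h.mismatches == 0

    def test_gu_pair_flag(self):
        arm = "ACGTACGA"
        arm2 = "TCGTACGT"  # full reverse complement of arm
        # introduce a G.U opportunity: pair arm[2]=G with T instead of C
        arm2_gu = arm2[:5] + "T" + arm2[6:]
        seq = "AA" + arm + "TTTT" + arm2_gu + "AA"
        with_gu = find_stem_loops(seq, min_stem=8, loop_range=(3, 6),
                                  allow_gu=True, max_mismatch=0)
        assert any(h.stem_len == 8 and h.mismatches == 0 for h in with_gu)
        without = find_stem_loops(seq, min_stem=8, loop_range=(3, 6),
                                  allow_gu=False, max_mismatch=1)
        assert any(h.stem_len == 8 and h.pairs == 7 and h.mismatches == 1
                   for h in without)

    def test_random_sequence_rarely_calls_long_stems(self):
        """Monte-Carlo null: strict 10 bp stems are rare in random 100-mers."""
        rng = np.random.default_rng(31)
        hits = 0
        n = 1000
        for _ in range(n):
            seq = _random_seq(rng, 100, np.array([0.25, 0.25, 0.25, 0.25]))
            calls = find_stem_loops(seq, min_stem=10, loop_range=(3, 20),
                                    allow_gu=False, max_mismatch=0)
            hits += bool(calls)
        assert hits / n < 0.02

    def test_empty_sequence(self):
        assert find_stem_loops("") == []


class TestControlRegionAnnotation:
    def test_planted_stem_loop_recovered(self):
        for seed in (0, 1, 2, 3, 4):
            cr, _, stem_loop, _ = generate_control_region(CRSpec(), seed)
            ann = annotate_control_region(cr, min_stem=8, max_mismatch=0)
            assert any(abs(h.start - stem_loop[0]) <= 10
                       for h in ann.stem_loops), seed

    def test_variable_domain_follows_elements(self):
        cr, _, _, _ = generate_control_region(CRSpec(), 2)
        ann = annotate_control_region(cr)
        assert ann.variable_domain is not None
        start, end = ann.variable_domain
        assert end == len(cr)
        assert start >= ann.at_block.end - 20
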