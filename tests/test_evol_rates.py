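import warnings
from itertools import permutations

import numpy as np
import pytest

from mitocomp import genetic_code as gc
from mitocomp.evol_rates import (gene_average_kaks, jukes_cantor,
                                 ng_site_counts, pairwise_kaks,
                                 pathway_differences)
from mitocomp.synthetic_data import EvolSpec, simulate_cds_pair


# ---- independent oracles, deliberately written as naive enumerations ------

def oracle_site_counts(codon, table_id=5):
    trans = gc.translation(table_id)
    stops = gc.stop_codons(table_id)
    syn = 0.0
    for pos in range(3):
        changes = [codon[:pos] + b + codon[pos + 1:]
                   for b in "ACGT" if b != codon[pos]]
        non_stop = [m for m in changes if m not in stops]
        if non_stop:
            syn += sum(trans[m] == trans[codon] for m in non_stop) / len(non_stop)
    return syn, 3.0 - syn


def oracle_pathway_counts(a, b, table_id=5):
    """Average (syn, nonsyn) steps over stop-free orderings of the changes."""
    trans = gc.translation(table_id)
    stops = gc.stop_codons(table_id)
    diff = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in permutations(diff):
        path = [a]
        for pos in order:
            path.append(path[-1][:pos] + b[pos] + path[-1][pos + 1:])
        if any(step in stops for step in path[1:]):
            continue
        sd = sum(trans[x] == trans[y] for x, y in zip(path, path[1:]))
        outcomes.append((sd, len(diff) - sd))
    if not outcomes:
        return None
    return (sum(o[0] for o in outcomes) / len(outcomes),
            sum(o[1] for o in outcomes) / len(outcomes))


class TestSiteCounts:
    def test_phe_third_position_only(self):
        # TTT: only TTC preserves Phe, at position 3
        syn, nonsyn = ng_site_counts("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(8 / 3)

    def test_met_under_invertebrate_code(self):
        # ATA is also Met under table 5
        syn, _ = ng_site_counts("ATG")
        assert syn == pytest.approx(1 / 3)

    def test_no_synonymous_neighbors(self):
        # AGG (Ser in table 5): neighbours AGA/AGC/AGT are Ser too, so pick
        # one that truly has none: TGG (Trp) pos1/2 changes all nonsyn,
        # but TGA is Trp in table 5, so use table 1 where TGG is isolated
        syn, _ = ng_site_counts("TGG", transl_table=1)
        assert syn == 0.0

    def test_sites_sum_to_three_for_every_sense_codon(self):
        for codon in gc.sense_codons(5):
            syn, nonsyn = ng_site_counts(codon)
            assert syn + nonsyn == pytest.approx(3.0)
            assert (syn, nonsyn) == pytest.approx(oracle_site_counts(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng_site_counts("TAA")


class TestPathwayCounts:
    def test_toy_pair_matches_enumeration(self):
        # TTT (Phe) -> CTC (Leu): two pathways, one syn + one nonsyn each
        assert pathway_differences("TTT", "CTC") == \
            pytest.approx(oracle_pathway_counts("TTT", "CTC"))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        sense = gc.sense_codons(5)
        for _ in range(50):
            a, b = rng.choice(sense, 2)
            assert pathway_differences(a, b) == \
                pytest.approx(pathway_differences(b, a))


class TestPairwiseKaks:
    def test_identical_sequences(self):
        est = pairwise_kaks("ATGAAATTT", "ATGAAATTT")
        assert est.ka == 0.0 and est.ks == 0.0
        assert est.ratio is None

    def test_three_codon_toy_pair(self):
        # one synonymous (TTT->TTC) and one nonsynonymous (AAA->GAA) change
        a, b = "ATGTTTAAA", "ATGTTCGAA"
        est = pairwise_kaks(a, b)
        s = sum(oracle_site_counts(c)[0] for c in ("ATG", "TTT", "AAA"))
        s2 = sum(oracle_site_counts(c)[0] for c in ("ATG", "TTC", "GAA"))
        S = (s + s2) / 2
        N = 9 - S
        assert est.ks == pytest.approx(jukes_cantor(1 / S))
        assert est.ka == pytest.approx(jukes_cantor(1 / N))

    def test_gap_and_stop_codons_are_missing_data(self):
        base = pairwise_kaks("ATGTTTAAA", "ATGTTCGAA")
        gapped = pairwise_kaks("ATGTTTAAA---", "ATGTTCGAA-AA")
        with_stop = pairwise_kaks("ATGTTTAAATAA", "ATGTTCGAAATT")
        assert gapped.ka == pytest.approx(base.ka)
        assert gapped.ks == pytest.approx(base.ks)
        assert with_stop.ka == pytest.approx(base.ka)

    def test_saturation_gives_missing(self):
        assert jukes_cantor(0.8) is None
        a = "TTT" * 30
        b = "AAA" * 30
        est = pairwise_kaks(a, b)
        assert est.ka is None and est.ratio is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pairwise_kaks("ATGTTT", "ATG")

    def test_agrees_with_independent_ng86_implementation(self):
        """Cross-check against Biopython's NG86 on simulated pairs."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from Bio.Data import CodonTable
        t5 = CodonTable.unambiguous_dna_by_id[5]
        for seed in (11, 12, 13):
            a, b = simulate_cds_pair(400, EvolSpec(omega=0.5,
                                                   branch_length=0.3,
                                                   seed=seed))
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86",
                               codon_table=t5)
            est = pairwise_kaks(a, b)
            # stop-codon handling details differ slightly between the two
            assert est.ka == pytest.approx(dn, rel=0.08, abs=0.01)
            assert est.ks == pytest.approx(ds, rel=0.08, abs=0.01)


class TestGeneAverages:
    def test_identical_alignments_are_excluded(self):
        alns = {"cox1": {"s1": "ATGAAATTT", "s2": "ATGAAATTT"}}
        with pytest.warns(UserWarning, match="cox1"):
            estimates, fit = gene_average_kaks(alns)
        assert estimates == [] and fit is None

    def test_pair_averaging_and_gc(self):
        a, b = simulate_cds_pair(300, EvolSpec(omega=0.3, branch_length=0.25,
                                               seed=5))
        c, _ = simulate_cds_pair(300, EvolSpec(omega=0.3, branch_length=0.25,
                                               seed=6))
        alns = {"nad2": {"x": a, "y": b, "z": c}}
        estimates, _ = gene_average_kaks(alns)
        (e,) = estimates
        assert e.n_pairs == 3
        pair_vals = [pairwise_kaks(p, q).ratio
                     for p, q in ((a, b), (a, c), (b, c))]
        assert e.ratio == pytest.approx(np.mean([v for v in pair_vals
                                                 if v is not None]))
        assert 0 < e.gc < 1

    def test_simulated_omega_recovery_single_gene(self):
        a, b = simulate_cds_pair(2000, EvolSpec(omega=0.5, branch_length=0.3,
                                                seed=21))
        est = pairwise_kaks(a, b)
        assert 0.35 < est.ratio < 0.65
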