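"""Nei–Gojobori (1986) Ka/Ks estimation.

Counting-based estimator: each codon position contributes a synonymous-site
fraction (the share of possible single-nucleotide changes at that position
that preserve the amino acid, with changes into stop codons excluded and the
denominator renormalised), observed differences between a codon pair are
averaged with equal weight over all minimal substitution pathways (pathways
crossing a stop codon are dropped and the remainder reweighted), and the
resulting proportions are corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − 4p/3).  A proportion at or beyond saturation (p >= 3/4)
yields a missing estimate, never a clamped one.

Ka/Ks < 1 indicates purifying selection, ≈ 1 neutrality, > 1 positive
selection.  Per-gene summaries average over all unordered sequence pairs of
an alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from . import genetic_code as gc
from .codon_usage import linear_fit

NUCS = "ACGT"


@dataclass
class RateEstimate:
    gene: str | None
    ka: float | None
    ks: float | None
    ratio: float | None
    n_pairs: int
    gc: float | None = None


def ng_site_counts(codon: str, transl_table: int = gc.DEFAULT_TABLE
                   ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    The two always sum to 3 (after the stop-exclusion renormalisation).
    """
    codon = codon.upper()
    stops = gc.stop_codons(transl_table)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    trans = gc.translation(transl_table)
    aa = trans[codon]
    syn = 0.0
    for pos in range(3):
        syn_changes = 0
        non_stop = 0
        for b in NUCS:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in stops:
                continue
            non_stop += 1
            if trans[mut] == aa:
                syn_changes += 1
        syn += syn_changes / non_stop if non_stop else 0.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _site_table(transl_table: int) -> dict[str, tuple[float, float]]:
    return {c: ng_site_counts(c, transl_table)
            for c in gc.sense_codons(transl_table)}


def pathway_differences(codon_a: str, codon_b: str,
                        transl_table: int = gc.DEFAULT_TABLE
                        ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged with equal weight over all minimal substitution pathways;
    pathways through stop codons are excluded and the rest renormalised.
    """
    a, b = codon_a.upper(), codon_b.upper()
    stops = gc.stop_codons(transl_table)
    if a in stops or b in stops:
        raise ValueError("stop codon in pathway endpoints")
    trans = gc.translation(transl_table)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    outcomes: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in stops:
                blocked = True
                break
            if trans[cur] == trans[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            outcomes.append((sd, nd))
    if not outcomes:
        raise ValueError(
            f"all substitution pathways between {a} and {b} cross a stop codon")
    sd = sum(o[0] for o in outcomes) / len(outcomes)
    nd = sum(o[1] for o in outcomes) / len(outcomes)
    return sd, nd


@lru_cache(maxsize=None)
def _diff_table(transl_table: int) -> dict[tuple[str, str], tuple[float, float]]:
    sense = gc.sense_codons(transl_table)
    table = {}
    for a in sense:
        for b in sense:
            table[(a, b)] = pathway_differences(a, b, transl_table)
    return table


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None at or beyond saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_kaks(cds_a: str, cds_b: str,
                  transl_table: int = gc.DEFAULT_TABLE) -> RateEstimate:
    """Nei–Gojobori Ka/Ks between two aligned CDS strings.

    Codon sites containing a gap, an N, or a stop codon in either sequence
    are treated as missing data and skipped pairwise.  Identical sequences
    give ka = ks = 0 with an undefined (None) ratio.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned CDS lengths differ")
    usable = len(a) - len(a) % 3
    sites = _site_table(transl_table)
    diffs = _diff_table(transl_table)
    s_a = s_b = n_a = n_b = 0.0
    sd = nd = 0.0
    gc_bases = 0
    all_bases = 0
    for i in range(0, usable, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in sites or cb not in sites:  # gap/N/stop codon: missing
            continue
        sa, na = sites[ca]
        sb, nb = sites[cb]
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d = diffs[(ca, cb)]
        sd += d[0]
        nd += d[1]
        gc_bases += sum(1 for ch in ca + cb if ch in "GC")
        all_bases += 6
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    if S == 0 and N == 0:
        raise ValueError("no comparable codon sites")
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return RateEstimate(gene=None, ka=ka, ks=ks, ratio=ratio, n_pairs=1,
                        gc=gc_bases / all_bases if all_bases else None)


def gene_average_kaks(per_gene_alignments: dict[str, dict[str, str]],
                      transl_table: int = gc.DEFAULT_TABLE,
                      gc_covariate: str = "all"
                      ) -> tuple[list[RateEstimate], tuple[float, float, float] | None]:
    """Per-gene mean Ka, Ks and Ka/Ks over all unordered sequence pairs.

    ``per_gene_alignments`` maps gene -> {taxon: aligned CDS}.  Genes whose
    estimates are all missing are excluded with a warning.  Returns the list
    of per-gene estimates plus the OLS fit of mean ratio against gene GC
    content (``gc_covariate``: "all" for total GC of the alignment, "gc3"
    for third positions), or None when fewer than 3 genes have a defined
    ratio.
    """
    import warnings

    estimates: list[RateEstimate] = []
    for gene, aln in per_gene_alignments.items():
        taxa = sorted(aln)
        if len(taxa) < 2:
            raise ValueError(f"{gene}: need >= 2 sequences")
        kas, kss, ratios = [], [], []
        for ta, tb in combinations(taxa, 2):
            est = pairwise_kaks(aln[ta], aln[tb], transl_table)
            if est.ka is not None:
                kas.append(est.ka)
            if est.ks is not None:
                kss.append(est.ks)
            if est.ratio is not None:
                ratios.append(est.ratio)
        if not ratios:
            warnings.warn(f"{gene}: all Ka/Ks estimates missing; excluded")
            continue
        gc_frac = _alignment_gc(aln, gc_covariate)
        estimates.append(RateEstimate(
            gene=gene,
            ka=sum(kas) / len(kas) if kas else None,
            ks=sum(kss) / len(kss) if kss else None,
            ratio=sum(ratios) / len(ratios),
            n_pairs=len(ratios),
            gc=gc_frac,
        ))
    fit = None
    pts = [(e.gc, e.ratio) for e in estimates
           if e.gc is not None and e.ratio is not None]
    if len(pts) >= 3 and len({p[0] for p in pts}) > 1:
        fit = linear_fit([p[0] for p in pts], [p[1] for p in pts])
    return estimates, fit


def _alignment_gc(aln: dict[str, str], covariate: str) -> float | None:
    gc_n = tot = 0
    for seq in aln.values():
        s = seq.upper()
        if covariate == "gc3":
            usable = len(s) - len(s) % 3
            s = s[2:usable:3]
        for ch in s:
            if ch in "ACGT":
                tot += 1
                if ch in "GC":
                    gc_n += 1
    return gc_n / tot if tot else None
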