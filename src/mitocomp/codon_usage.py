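"""Codon usage bias: codon counting, RSCU, ENC, CBI and GC correlates.

The effective number of codons (ENC) follows Wright's homozygosity
formulation, generalised to the degeneracy layout of the genetic code in
force.  Under the invertebrate mitochondrial code (table 5) the 62 sense
codons partition into 12 two-fold, 6 four-fold, one six-fold (Leu) and one
eight-fold (Ser, TCN+AGN) family, so ENC ranges from 20 (one codon per
residue) to 62 (uniform usage) — not Wright's universal-code 61.

The codon bias index (CBI) measures excess usage of one preferred codon per
family: CBI = (N_pref − N_rand)/(N_tot − N_rand), where N_rand is the count
expected under uniform within-family usage.  CBI is 0 for uniform usage and
1 when only preferred codons are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as _scipy_stats

from . import genetic_code as gc


@dataclass
class CodonUsageTable:
    transl_table: int
    counts: dict[str, int]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)
    dropped: int = 0  # codons containing N, skipped from the tallies

    def __post_init__(self) -> None:
        if not self.families:
            self.families = gc.synonymous_families(self.transl_table)
        n_codons = sum(len(c) for c in self.families.values())
        if n_codons != len(gc.sense_codons(self.transl_table)):
            raise ValueError("family sizes do not cover the sense codons")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative codon count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts.get(c, 0) for c in self.families[aa]}


@dataclass
class CodonBiasSummary:
    enc: float
    cbi: float | None
    gc_all: float
    gc3: float
    at_ending: float
    unused: set[str]


class InternalStopError(ValueError):
    pass


def count_codons(cds_set: list[str], transl_table: int = gc.DEFAULT_TABLE,
                 names: list[str] | None = None) -> CodonUsageTable:
    """Tally sense codons over a set of CDS nucleotide strings.

    A truncated terminal stop (T or TA remainder) is dropped, as is a final
    full stop codon.  An internal stop raises, naming the offending gene and
    codon position.  Codons containing N are skipped and counted in
    ``dropped``.
    """
    stops = gc.stop_codons(transl_table)
    counts: dict[str, int] = {}
    dropped = 0
    for idx, cds in enumerate(cds_set):
        label = names[idx] if names else f"cds[{idx}]"
        seq = cds.upper()
        rem = len(seq) % 3
        if rem:
            tail = seq[-rem:]
            if tail in ("T", "TA"):
                seq = seq[:-rem]
            else:
                raise ValueError(
                    f"{label}: length {len(seq)} not divisible by 3 and tail "
                    f"{tail!r} is not a truncated stop")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in stops:
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if "N" in codon:
                dropped += 1
                continue
            if codon in stops:
                raise InternalStopError(
                    f"{label}: internal stop codon {codon} at codon {pos + 1}")
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(transl_table=transl_table, counts=counts,
                           dropped=dropped)


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage; None for codons of unobserved families."""
    out: dict[str, float | None] = {}
    for aa, codons in table.families.items():
        k = len(codons)
        fam_total = sum(table.counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = (table.counts.get(c, 0) * k / fam_total) if fam_total else None
    return out


def enc(table: CodonUsageTable) -> float:
    """Wright-style effective number of codons for the table's genetic code.

    Per family with n >= 2 codons observed, the homozygosity
    F = (n * sum p_i^2 - 1) / (n - 1); ENC sums (number of families in each
    degeneracy class) / (mean F of the class).  A class with no estimable F
    is imputed at the no-bias floor F = 1/k.  The result is clamped to the
    number of sense codons.
    """
    if table.total == 0:
        raise ValueError("empty codon usage table")
    f_by_class: dict[int, list[float]] = {}
    for aa, codons in table.families.items():
        k = len(codons)
        fam = [table.counts.get(c, 0) for c in codons]
        n = sum(fam)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in fam)
        f = (n * sum_p2 - 1) / (n - 1)
        f_by_class.setdefault(k, []).append(f)
    classes = gc.degeneracy_classes(table.transl_table)
    total = 0.0
    for k, n_families in classes.items():
        fs = f_by_class.get(k, [])
        fbar = sum(fs) / len(fs) if fs else 1.0 / k
        if fbar <= 0:
            fbar = 1.0 / k  # all-singleton usage gives F=0; fall back to floor
        total += n_families / fbar
    max_enc = float(len(gc.sense_codons(table.transl_table)))
    return min(total, max_enc)


def modal_codons(table: CodonUsageTable) -> dict[str, str]:
    """The most-used codon of each family (ties broken alphabetically)."""
    out = {}
    for aa, codons in table.families.items():
        out[aa] = max(sorted(codons), key=lambda c: table.counts.get(c, 0))
    return out


def cbi(table: CodonUsageTable,
        preferred: dict[str, str] | None = None) -> float | None:
    """Codon bias index; ``preferred`` maps amino acid -> preferred codon.

    Defaults to the table's own modal codons.  Returns None when the table
    is degenerate (N_tot == N_rand, i.e. no codons observed).
    """
    if preferred is None:
        preferred = modal_codons(table)
    n_pref = 0
    n_rand = 0.0
    n_tot = 0
    for aa, codons in table.families.items():
        k = len(codons)
        fam_n = sum(table.counts.get(c, 0) for c in codons)
        pref = preferred.get(aa)
        if pref is not None and pref not in codons:
            raise ValueError(f"preferred codon {pref} is not in the {aa} family")
        n_pref += table.counts.get(pref, 0) if pref else 0
        n_rand += fam_n / k
        n_tot += fam_n
    if n_tot == 0 or abs(n_tot - n_rand) < 1e-12:
        return None
    return (n_pref - n_rand) / (n_tot - n_rand)


def at_ending_fraction(table: CodonUsageTable) -> float:
    """Fraction of counted codons whose third base is A or T."""
    if table.total == 0:
        raise ValueError("empty codon usage table")
    at = sum(n for c, n in table.counts.items() if c[2] in "AT")
    return at / table.total


def gc_content_of_table(table: CodonUsageTable) -> float:
    """GC fraction over all bases of the counted codons."""
    total_bases = 3 * table.total
    if total_bases == 0:
        raise ValueError("empty codon usage table")
    gc_bases = sum(n * sum(1 for b in c if b in "GC")
                   for c, n in table.counts.items())
    return gc_bases / total_bases


def gc3(table: CodonUsageTable) -> float:
    if table.total == 0:
        raise ValueError("empty codon usage table")
    g = sum(n for c, n in table.counts.items() if c[2] in "GC")
    return g / table.total


def unused_codons(table: CodonUsageTable) -> set[str]:
    """Sense codons with zero observed count."""
    return {c for c in gc.sense_codons(table.transl_table)
            if table.counts.get(c, 0) == 0}


def summarize(table: CodonUsageTable,
              preferred: dict[str, str] | None = None) -> CodonBiasSummary:
    return CodonBiasSummary(
        enc=enc(table),
        cbi=cbi(table, preferred),
        gc_all=gc_content_of_table(table),
        gc3=gc3(table),
        at_ending=at_ending_fraction(table),
        unused=unused_codons(table),
    )


def linear_fit(x: list[float], y: list[float]) -> tuple[float, float, float]:
    """Ordinary least squares (slope, intercept, r_squared)."""
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(set(x)) == 1:
        raise ValueError("x is constant")
    res = _scipy_stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2
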