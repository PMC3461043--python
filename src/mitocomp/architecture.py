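"""Genome-architecture statistics: gene overlaps, non-coding regions and
start/stop codon classes.

Insect mitogenomes are tightly packed: neighbouring genes frequently overlap
by a few base pairs (the atp8–atp6 and nad4–nad4L junctions classically share
a 7 bp ATGATAA motif in which one gene's start codon is nested in the other's
stop), and several protein-coding genes end on truncated T/TA stops completed
by post-transcriptional polyadenylation.  The operations here derive those
observations from an annotated :class:`~mitocomp.io.MitoGenome`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import revcomp, stop_codons
from .io import GeneFeature, MitoGenome, feature_sequence

DEFAULT_LARGE_NC = 100  # bp; regions longer than this are flagged "large"


@dataclass
class OverlapRecord:
    """Two genes adjacent in genome order whose spans intersect on the circle."""

    gene_a: str
    gene_b: str
    length: int
    sequence: str  # shared stretch on the J-strand
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("overlap length must be >= 1")
        if len(self.sequence) != self.length:
            raise ValueError("overlap sequence length mismatch")


@dataclass
class NCRegion:
    flank_a: str
    flank_b: str
    start: int
    end: int
    length: int
    is_large: bool
    label: str | None = None


@dataclass
class StartStopRecord:
    gene: str
    start_codon: str
    stop_codon: str
    truncated: bool
    anomaly: str | None = None

    def __post_init__(self) -> None:
        if self.truncated and self.stop_codon not in ("TA", "T"):
            raise ValueError("truncated stop must be TA or T")


def _sorted_genes(genome: MitoGenome) -> list[GeneFeature]:
    """Gene features (PCG/tRNA/rRNA) in J-strand start order."""
    return sorted(genome.genes(), key=lambda f: (f.start, f.end))


def _unrolled(f: GeneFeature, L: int) -> tuple[int, int]:
    """(start, end) with wrap features unrolled past L."""
    return (f.start, f.end + L if f.wraps else f.end)


def find_gene_overlaps(genome: MitoGenome) -> list[OverlapRecord]:
    """Intersections between genes adjacent in J-strand order.

    Overlaps are counted pairwise between neighbours regardless of strand;
    the pair closing the circle (last gene vs first) is included.  Returns an
    empty list when no genes overlap.
    """
    genes = _sorted_genes(genome)
    L = len(genome)
    res = genome.seq.residues
    records: list[OverlapRecord] = []
    n = len(genes)
    if n < 2:
        return records
    for i in range(n):
        a = genes[i]
        b = genes[(i + 1) % n]
        a_start, a_end = _unrolled(a, L)
        b_start, b_end = _unrolled(b, L)
        if i + 1 == n:  # wrap-around adjacency
            b_start += L
            b_end += L
        ov = a_end - b_start
        if ov >= 1 and b_start < a_end:
            ov = min(ov, b_end - b_start, a_end - a_start)
            s = b_start % L
            e = (b_start + ov) % L
            seq = res[s:] + res[:e] if e <= s else res[s:s + ov]
            records.append(OverlapRecord(gene_a=a.name, gene_b=b.name,
                                         length=ov, sequence=seq,
                                         start=s, end=(s + ov) % L or (s + ov)))
    return records


def find_noncoding_regions(genome: MitoGenome,
                           min_large: int = DEFAULT_LARGE_NC) -> list[NCRegion]:
    """Complement of the gene-feature union on the circle.

    Only PCG/tRNA/rRNA features count as coding cover, so an annotated
    control region is rediscovered as a non-coding region.  The region
    between rrnS and trnI is labelled "CR".
    """
    genes = _sorted_genes(genome)
    if not genes:
        raise ValueError(f"{genome.id}: genome has no gene features")
    L = len(genome)
    covered = bytearray(L)
    for f in genes:
        if f.wraps:
            for i in range(f.start, L):
                covered[i] = 1
            for i in range(f.end):
                covered[i] = 1
        else:
            for i in range(f.start, f.end):
                covered[i] = 1
    regions: list[NCRegion] = []
    if all(covered):
        return regions

    # maximal uncovered runs on the circle
    runs: list[tuple[int, int]] = []  # [start, end) possibly wrapping
    i = 0
    # rotate to start inside a covered position so runs never split at origin
    anchor = covered.index(1)
    pos = anchor
    seen = 0
    run_start = None
    while seen <= L:
        p = pos % L
        if not covered[p] and run_start is None:
            run_start = p
        elif covered[p] and run_start is not None:
            runs.append((run_start, p))
            run_start = None
        pos += 1
        seen += 1

    def flank_before(start: int) -> str:
        best, best_d = "?", None
        for f in genes:
            e = f.end % L
            d = (start - e) % L
            if best_d is None or d < best_d:
                best, best_d = f.name, d
        return best

    def flank_after(end: int) -> str:
        best, best_d = "?", None
        for f in genes:
            s = f.start
            d = (s - end) % L
            if best_d is None or d < best_d:
                best, best_d = f.name, d
        return best

    for s, e in runs:
        # linearise: end in (s, s+L]; regions touching position L are not wraps
        e_lin = e if e > s else e + L
        e = e_lin if e_lin <= L else e_lin - L
        length = e_lin - s
        fa, fb = flank_before(s), flank_after(e)
        label = "CR" if (fa, fb) == ("rrnS", "trnI") else None
        regions.append(NCRegion(flank_a=fa, flank_b=fb, start=s, end=e,
                                length=length, is_large=length > min_large,
                                label=label))
    regions.sort(key=lambda r: r.start)
    return regions


def total_noncoding_length(genome: MitoGenome,
                           min_large: int = DEFAULT_LARGE_NC) -> int:
    return sum(r.length for r in find_noncoding_regions(genome, min_large))


def classify_terminal_codons(genome: MitoGenome) -> list[StartStopRecord]:
    """Start and stop codon of every protein-coding gene.

    A stop is called truncated (T or TA) when the CDS length modulo 3 leaves
    that remainder and a tRNA abuts the gene immediately downstream in coding
    orientation (0 bp gap) — the configuration in which polyadenylation can
    complete the terminator.  Otherwise the record is flagged as an
    annotation anomaly.
    """
    genes = _sorted_genes(genome)
    L = len(genome)
    records = []
    for f in genome.genes("PCG"):
        cds = feature_sequence(genome, f)
        if len(cds) < 6:
            raise ValueError(f"{f.name}: CDS shorter than 6 nt")
        start_codon = cds[:3]
        rem = len(cds) % 3
        anomaly = None
        if rem == 0:
            stop = cds[-3:]
            truncated = False
            if stop not in stop_codons(genome.transl_table):
                anomaly = f"final codon {stop} is not a stop"
        else:
            tail = cds[-rem:]
            if tail in ("T", "TA") and _abuts_downstream_trna(genome, f, genes, L):
                stop, truncated = tail, True
            else:
                stop, truncated = tail, False
                anomaly = (f"{rem} nt remainder {tail!r} without an abutting "
                           "downstream tRNA")
        records.append(StartStopRecord(gene=f.name, start_codon=start_codon,
                                       stop_codon=stop, truncated=truncated,
                                       anomaly=anomaly))
    return records


def _abuts_downstream_trna(genome: MitoGenome, f: GeneFeature,
                           genes: list[GeneFeature], L: int) -> bool:
    """True if a tRNA starts exactly where f ends, in f's coding direction."""
    if f.strand == "J":
        boundary = f.end % L
        return any(g.kind == "tRNA" and g.start == boundary for g in genes)
    boundary = f.start
    return any(g.kind == "tRNA" and g.end % L == boundary for g in genes)


def shared_overlap_motif(genomes: list[MitoGenome],
                         gene_pair: tuple[str, str]):
    """The overlap sequence of a gene pair across genomes.

    Returns the motif string when identical in every genome possessing the
    overlap, a {genome id: sequence} dict when they differ, and None when the
    pair overlaps nowhere.  Sequences are oriented to the genes' coding
    strand when both members lie on the N-strand.
    """
    found: dict[str, str] = {}
    for g in genomes:
        for rec in find_gene_overlaps(g):
            if {rec.gene_a, rec.gene_b} == set(gene_pair):
                seq = rec.sequence
                fa, fb = g.get(rec.gene_a), g.get(rec.gene_b)
                if fa and fb and fa.strand == "N" and fb.strand == "N":
                    seq = revcomp(seq)
                found[g.id] = seq
    if not found:
        return None
    values = set(found.values())
    if len(values) == 1:
        return values.pop()
    return found
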