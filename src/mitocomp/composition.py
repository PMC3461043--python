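"""Nucleotide composition and strand-skew statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed over a
partition of the genome (whole sequence, concatenated PCGs/tRNAs/rRNAs,
third codon positions, or the control region).  Published mitogenome
composition tables are conventionally reported on the J-strand, so partition
sequences are concatenated in genome order on the J-strand by default; a
flag switches per-gene sequences to their coding strands (which flips skew
signs for N-strand genes).
"""

from __future__ import annotations

from dataclasses import dataclass

from .architecture import find_noncoding_regions
from .genetic_code import revcomp
from .io import MitoGenome, feature_sequence

PARTITIONS = ("whole", "PCG", "tRNA", "rRNA", "codon3", "CR")


@dataclass
class PartitionStats:
    partition: str
    length: int            # counted residues (N excluded)
    counts: dict[str, int]  # A/C/G/T tallies
    at_content: float
    at_skew: float | None  # None when A+T == 0
    gc_skew: float | None  # None when G+C == 0


def composition_stats(seq: str, partition: str = "whole") -> PartitionStats:
    """Counts, AT content and both skews of a nucleotide string (N ignored)."""
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty partition (no A/C/G/T residues)")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at = a + t
    gc = g + c
    return PartitionStats(
        partition=partition,
        length=total,
        counts=counts,
        at_content=at / total,
        at_skew=(a - t) / at if at else None,
        gc_skew=(g - c) / gc if gc else None,
    )


def partition_sequence(genome: MitoGenome, partition: str,
                       coding_strand: bool | None = None) -> str:
    """The nucleotide string a partition resolves to.

    whole: the full J-strand.  PCG/tRNA/rRNA: genes of that kind concatenated
    in genome order — J-strand slices by default (the convention composition
    tables are published in), coding-strand sequences if ``coding_strand``.
    codon3: third codon positions of all PCGs, read on their coding strands
    by default (the frame is only defined there); ``coding_strand=False``
    complements the thirds of N-strand genes back onto the J-strand, which
    flips their skew signs.  CR: the region between rrnS and trnI.
    """
    res = genome.seq.residues
    if partition == "whole":
        return res
    if partition in ("PCG", "tRNA", "rRNA"):
        on_coding = bool(coding_strand)  # default: J-strand
        parts = []
        for f in sorted(genome.genes(partition), key=lambda x: x.start):
            seq = feature_sequence(genome, f)
            if not on_coding and f.strand == "N":
                seq = revcomp(seq)
            parts.append(seq)
        if not parts:
            raise ValueError(f"{genome.id}: no {partition} features")
        return "".join(parts)
    if partition == "codon3":
        on_coding = True if coding_strand is None else coding_strand
        thirds = []
        for f in sorted(genome.genes("PCG"), key=lambda x: x.start):
            cds = feature_sequence(genome, f)
            usable = len(cds) - len(cds) % 3
            third = cds[2:usable:3]
            if not on_coding and f.strand == "N":
                # project back to the J-strand: complement without reversing,
                # so the tally matches the J-strand bases at those positions
                third = third.translate(str.maketrans("ACGTN", "TGCAN"))
            thirds.append(third)
        if not thirds:
            raise ValueError(f"{genome.id}: no PCG features")
        return "".join(thirds)
    if partition == "CR":
        for region in find_noncoding_regions(genome):
            if region.label == "CR":
                if region.end >= region.start:
                    return res[region.start:region.end]
                return res[region.start:] + res[:region.end]
        raise ValueError(f"{genome.id}: no CR (rrnS..trnI region) found")
    raise ValueError(f"unknown partition {partition!r}")


def partition_composition(genome: MitoGenome, partition: str,
                          coding_strand: bool | None = None) -> PartitionStats:
    seq = partition_sequence(genome, partition, coding_strand=coding_strand)
    return composition_stats(seq, partition)


def merge_stats(stats: list[PartitionStats], label: str = "merged") -> PartitionStats:
    """Length-weighted merge of several partitions (count addition)."""
    counts = {b: sum(s.counts[b] for s in stats) for b in "ACGT"}
    merged_seq = "".join(b * counts[b] for b in "ACGT")
    return composition_stats(merged_seq, label)


def sliding_window_profile(genome: MitoGenome, window: int, step: int,
                           metric: str = "gc_content") -> list[tuple[float, float]]:
    """Circular sliding-window profile as deviation from the genome mean.

    Returns (window midpoint, metric deviation) per step.  Windows wrap
    around the origin.  Skew metrics yield 0 deviation for windows whose
    skew is undefined.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(genome)
    if window > L:
        raise ValueError("window exceeds genome length")
    if step < 1:
        raise ValueError("step must be >= 1")
    res = genome.seq.residues
    whole = composition_stats(res)
    if metric == "gc_content":
        mean = 1.0 - whole.at_content

        def value(s: PartitionStats) -> float:
            return 1.0 - s.at_content
    elif metric == "gc_skew":
        mean = whole.gc_skew or 0.0

        def value(s: PartitionStats) -> float:
            return s.gc_skew if s.gc_skew is not None else mean
    elif metric == "at_content":
        mean = whole.at_content

        def value(s: PartitionStats) -> float:
            return s.at_content
    else:
        raise ValueError(f"unknown metric {metric!r}")
    doubled = res + res
    out = []
    for start in range(0, L, step):
        w = composition_stats(doubled[start:start + window])
        mid = (start + window / 2.0) % L
        out.append((mid, value(w) - mean))
    return out
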