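"""Translation-table helpers shared across the package.

Everything here is derived from Biopython's NCBI codon tables; the default is
table 5 (invertebrate mitochondrial), under which AGA/AGG encode serine,
ATA encodes methionine and TGA encodes tryptophan, leaving 62 sense codons
and only TAA/TAG as stops.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
DEFAULT_TABLE = 5

ALL_CODONS = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=3))


@lru_cache(maxsize=None)
def codon_table(table_id: int = DEFAULT_TABLE) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@lru_cache(maxsize=None)
def stop_codons(table_id: int = DEFAULT_TABLE) -> frozenset[str]:
    return frozenset(codon_table(table_id).stop_codons)


@lru_cache(maxsize=None)
def sense_codons(table_id: int = DEFAULT_TABLE) -> tuple[str, ...]:
    stops = stop_codons(table_id)
    return tuple(c for c in ALL_CODONS if c not in stops)


@lru_cache(maxsize=None)
def translation(table_id: int = DEFAULT_TABLE) -> dict[str, str]:
    """Map each sense codon to its one-letter amino acid."""
    return dict(codon_table(table_id).forward_table)


@lru_cache(maxsize=None)
def synonymous_families(table_id: int = DEFAULT_TABLE) -> dict[str, tuple[str, ...]]:
    """Amino acid -> sorted tuple of its sense codons (one family per residue)."""
    fams: dict[str, list[str]] = {}
    for codon, aa in translation(table_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cods)) for aa, cods in sorted(fams.items())}


@lru_cache(maxsize=None)
def degeneracy_classes(table_id: int = DEFAULT_TABLE) -> dict[int, int]:
    """Family size -> number of families of that size (e.g. {2: 12, 4: 6, 6: 1, 8: 1})."""
    classes: dict[int, int] = {}
    for cods in synonymous_families(table_id).values():
        classes[len(cods)] = classes.get(len(cods), 0) + 1
    return dict(sorted(classes.items()))


def translate_codon(codon: str, table_id: int = DEFAULT_TABLE) -> str:
    return translation(table_id)[codon]


def is_stop(codon: str, table_id: int = DEFAULT_TABLE) -> bool:
    return codon in stop_codons(table_id)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
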