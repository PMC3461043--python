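"""Reading and writing annotated mitochondrial genomes.

A :class:`MitoGenome` couples a circular nucleotide sequence with an ordered
list of typed, stranded gene features.  Internally all coordinates are 0-based
half-open intervals on the J-strand (the majority coding strand, defined as
the strand carrying *cox1*); features that cross the origin of the circle
carry a ``wraps`` flag and satisfy ``start > end`` in the linearised frame.
All report output uses 1-based inclusive coordinates (GenBank convention).

GenBank flat files are parsed and written through Biopython; a plain TSV
feature table (name, kind, strand, start, end, 1-based inclusive) is accepted
as an alternative annotation source next to a FASTA sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genetic_code import revcomp

VALID_ALPHABET = frozenset("ACGTN")
FEATURE_KINDS = ("PCG", "tRNA", "rRNA", "NC", "CR")


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


class CoordinateError(ValueError):
    """Raised when feature coordinates fall outside the sequence."""


@dataclass
class CircularSequence:
    """An uppercase A/C/G/T/N nucleotide string on a (usually) circular molecule."""

    residues: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(f"invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneFeature:
    """A typed, stranded annotation on the J-strand coordinate frame.

    ``strand`` is "J" or "N"; ``wraps`` marks features crossing the circle
    origin, in which case the occupied interval is [start, L) + [0, end).
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    wraps: bool = False
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if not self.wraps and not self.start < self.end:
            raise CoordinateError(
                f"{self.name}: start must be < end unless the feature wraps"
            )
        if self.name.startswith("trn") and self.kind != "tRNA":
            raise ValueError(f"{self.name}: trn* names must have kind tRNA")
        if self.name.startswith("rrn") and self.kind != "rRNA":
            raise ValueError(f"{self.name}: rrn* names must have kind rRNA")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if genome_length is None:
            raise CoordinateError(f"{self.name}: wrap feature needs genome length")
        return (genome_length - self.start) + self.end


@dataclass
class MitoGenome:
    """A circular mitogenome: sequence plus ordered feature annotations."""

    id: str
    seq: CircularSequence
    features: list[GeneFeature] = field(default_factory=list)
    transl_table: int = 5

    def __post_init__(self) -> None:
        L = len(self.seq)
        for f in self.features:
            if f.start < 0 or f.start >= L or f.end < 0 or f.end > L:
                raise CoordinateError(
                    f"{f.name}: coordinates ({f.start}, {f.end}) outside sequence "
                    f"of length {L}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def genes(self, kind: str | None = None) -> list[GeneFeature]:
        """Features of one kind, or all gene features (PCG/tRNA/rRNA) if None."""
        if kind is None:
            return [f for f in self.features if f.kind in ("PCG", "tRNA", "rRNA")]
        return [f for f in self.features if f.kind == kind]

    def get(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


# --- canonical gene-name synonyms -----------------------------------------
#
# Keys are upper-cased, punctuation-stripped dialect names as found in GenBank
# gene/product qualifiers.  The table is deliberately extensible: callers may
# pass extra synonyms to read_genbank.  Leucine/serine isoacceptor numbering
# follows the usual mitogenome-map convention L1: UUR, L2: CUN, S1: AGN,
# S2: UCN.

_BASE_SYNONYMS = {
    "COI": "cox1", "COXI": "cox1", "CO1": "cox1", "COX1": "cox1",
    "COII": "cox2", "COXII": "cox2", "CO2": "cox2", "COX2": "cox2",
    "COIII": "cox3", "COXIII": "cox3", "CO3": "cox3", "COX3": "cox3",
    "CYTB": "cytb", "COB": "cytb", "CYB": "cytb",
    "ATP6": "atp6", "ATPASE6": "atp6", "ATPASE 6": "atp6",
    "ATP8": "atp8", "ATPASE8": "atp8", "ATPASE 8": "atp8",
    "ND1": "nad1", "NADH1": "nad1", "NAD1": "nad1",
    "ND2": "nad2", "NADH2": "nad2", "NAD2": "nad2",
    "ND3": "nad3", "NADH3": "nad3", "NAD3": "nad3",
    "ND4": "nad4", "NADH4": "nad4", "NAD4": "nad4",
    "ND4L": "nad4L", "NADH4L": "nad4l", "NAD4L": "nad4L",
    "ND5": "nad5", "NADH5": "nad5", "NAD5": "nad5",
    "ND6": "nad6", "NADH6": "nad6", "NAD6": "nad6",
    "16S": "rrnL", "16S RRNA": "rrnL", "RRNL": "rrnL", "L-RRNA": "rrnL",
    "LARGE SUBUNIT RIBOSOMAL RNA": "rrnL", "16S RIBOSOMAL RNA": "rrnL",
    "12S": "rrnS", "12S RRNA": "rrnS", "RRNS": "rrnS", "S-RRNA": "rrnS",
    "SMALL SUBUNIT RIBOSOMAL RNA": "rrnS", "12S RIBOSOMAL RNA": "rrnS",
    "D-LOOP": "CR", "CONTROL REGION": "CR", "A+T-RICH REGION": "CR", "CR": "CR",
}

_TRNA_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_TRNA_NAME = {
    "A": "trnA", "R": "trnR", "N": "trnN", "D": "trnD", "C": "trnC",
    "Q": "trnQ", "E": "trnE", "G": "trnG", "H": "trnH", "I": "trnI",
    "K": "trnK", "M": "trnM", "F": "trnF", "P": "trnP", "T": "trnT",
    "W": "trnW", "Y": "trnY", "V": "trnV",
}


def canonical_gene_name(raw: str, feature_type: str = "",
                        extra_synonyms: dict[str, str] | None = None) -> str | None:
    """Map an annotation-dialect gene name to its canonical label, or None."""
    name = raw.strip()
    key = name.upper()
    table = dict(_BASE_SYNONYMS)
    if extra_synonyms:
        table.update({k.upper(): v for k, v in extra_synonyms.items()})
    if key in table:
        return table[key]
    low = name.lower()
    if low in ("cox1", "cox2", "cox3", "cytb", "atp6", "atp8", "nad1", "nad2",
               "nad3", "nad4", "nad4l", "nad5", "nad6", "rrnl", "rrns"):
        return low if low != "nad4l" else "nad4L"
    # short canonical names (trnA, trnL1, ...) — but not tRNA-Xxx products
    if (low.startswith("trn") and 4 <= len(name) <= 5 and "-" not in name
            and " " not in name):
        core = name[3:]
        return "trn" + core[0].upper() + core[1:]
    # tRNA-Leu(UUR) style product names
    up = key.replace("TRNA-", "").replace("TRNA ", "").replace("TRNA", "")
    for aa3, aa1 in _TRNA_AA.items():
        if up.startswith(aa3):
            rest = up[len(aa3):].strip("()- ")
            if aa1 == "L":
                if "CUN" in rest:
                    return "trnL2"
                return "trnL1"
            if aa1 == "S":
                if "UCN" in rest or "TCN" in rest:
                    return "trnS2"
                return "trnS1"
            return _TRNA_NAME[aa1]
    return None


def _feature_kind(bio_type: str, name: str | None) -> str | None:
    if bio_type == "CDS":
        return "PCG"
    if bio_type == "tRNA":
        return "tRNA"
    if bio_type == "rRNA":
        return "rRNA"
    if bio_type in ("D-loop", "misc_feature"):
        if name == "CR":
            return "CR"
        return "NC"
    return None


def read_genbank(path: str | Path,
                 extra_synonyms: dict[str, str] | None = None) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Gene names are normalised via the synonym table; strands are recorded as
    J/N relative to the strand carrying cox1 (falling back to the majority
    strand).  If cox1 sits on the file's reverse strand the whole genome is
    reverse-complemented so that the J-strand is the stored sequence.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted ValueError subtypes
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    return _genome_from_record(record, extra_synonyms)


def _genome_from_record(record: SeqRecord,
                        extra_synonyms: dict[str, str] | None = None) -> MitoGenome:
    L = len(record.seq)
    if L == 0:
        raise FormatError(f"{record.id}: record has no sequence")
    raw_feats: list[tuple[str, str, int, int, int, bool, str | None, int | None]] = []
    transl_table = 5
    for feat in record.features:
        qual = feat.qualifiers
        raw = (qual.get("gene") or qual.get("product") or qual.get("note") or [""])[0]
        name = canonical_gene_name(raw, feat.type, extra_synonyms)
        kind = _feature_kind(feat.type, name)
        if kind is None:
            continue
        if name is None:
            if feat.type in ("D-loop",):
                name = "CR"
                kind = "CR"
            else:
                warnings.warn(f"{record.id}: unknown gene name {raw!r}; kept as NC")
                name = raw or "unknown"
                kind = "NC"
        if feat.type == "CDS" and "transl_table" in qual:
            transl_table = int(qual["transl_table"][0])
        loc = feat.location
        strand = loc.strand if loc.strand is not None else 1
        wraps = False
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            p0, p1 = loc.parts
            if int(p0.end) == L and int(p1.start) == 0:
                start, end, wraps = int(p0.start), int(p1.end), True
            else:
                start, end = int(loc.start), int(loc.end)
        else:
            start, end = int(loc.start), int(loc.end)
        if start < 0 or end > L:
            raise CoordinateError(
                f"{record.id}:{name} coordinates ({start}, {end}) outside 1..{L}")
        anticodon = None
        if "anticodon" in qual:
            ac = qual["anticodon"][0]
            # e.g. "(pos:14..16,aa:Ile,seq:gat)" or a bare triplet
            if "seq:" in ac:
                anticodon = ac.split("seq:")[1].strip(") ").upper()
            elif len(ac.strip()) == 3:
                anticodon = ac.strip().upper()
        raw_feats.append((name, kind, start, end, strand, wraps, anticodon, None))

    # orient: J-strand is the strand carrying cox1, else the majority strand
    cox1 = [f for f in raw_feats if f[0] == "cox1"]
    if cox1:
        j_sign = cox1[0][4]
    else:
        plus = sum(1 for f in raw_feats if f[4] >= 0)
        j_sign = 1 if plus * 2 >= len(raw_feats) else -1

    seq = str(record.seq).upper()
    if j_sign < 0:
        seq = revcomp(seq)
        # mirror p -> L-p maps [s,e) to [L-e, L-s); a wrap interval stays a wrap
        raw_feats = [(name, kind, L - end, L - start, -strand, wraps, anticodon, None)
                     for name, kind, start, end, strand, wraps, anticodon, _
                     in raw_feats]

    features = [
        GeneFeature(name=name, kind=kind, strand="J" if strand >= 0 else "N",
                    start=start, end=end, wraps=wraps, anticodon=anticodon)
        for name, kind, start, end, strand, wraps, anticodon, _ in raw_feats
    ]
    features.sort(key=lambda f: (f.start, f.end))
    return MitoGenome(id=record.id, seq=CircularSequence(seq),
                      features=features, transl_table=transl_table)


_KIND_TO_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "NC": "misc_feature", "CR": "D-loop"}


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Serialise a MitoGenome as a GenBank flat file (round-trip safe)."""
    L = len(genome)
    record = SeqRecord(Seq(genome.seq.residues), id=genome.id, name=genome.id[:16],
                       description="mitochondrial genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.seq.is_circular else "linear"
    for f in genome.features:
        sign = 1 if f.strand == "J" else -1
        if f.wraps:
            loc = CompoundLocation([FeatureLocation(f.start, L, sign),
                                    FeatureLocation(0, f.end, sign)])
        else:
            loc = FeatureLocation(f.start, f.end, sign)
        qual: dict[str, list[str]] = {"gene": [f.name]}
        if f.kind == "PCG":
            qual["transl_table"] = [str(genome.transl_table)]
        if f.anticodon:
            qual["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_KIND_TO_TYPE[f.kind],
                                          qualifiers=qual))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_feature_table(path: str | Path, seq: str, genome_id: str = "genome",
                       transl_table: int = 5) -> MitoGenome:
    """Build a MitoGenome from a sequence plus a TSV feature table.

    Columns: name, kind, strand (J/N), start, end — 1-based inclusive; a
    feature crossing the origin has start > end.
    """
    features = []
    L = len(seq)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"feature table row needs 5 columns: {line!r}")
            name, kind, strand = parts[0], parts[1], parts[2]
            start1, end1 = int(parts[3]), int(parts[4])
            wraps = start1 > end1
            features.append(GeneFeature(
                name=name, kind=kind, strand=strand,
                start=start1 - 1, end=end1, wraps=wraps,
                anticodon=parts[5] if len(parts) > 5 and parts[5] else None))
    features.sort(key=lambda f: (f.start, f.end))
    return MitoGenome(id=genome_id, seq=CircularSequence(seq),
                      features=features, transl_table=transl_table)


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tstrand\tstart\tend\tanticodon\n")
        for f in genome.features:
            start1 = f.start + 1
            end1 = f.end
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{start1}\t{end1}\t"
                     f"{f.anticodon or ''}\n")


def feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """5'->3' sequence of a feature on its coding strand.

    Origin-spanning features concatenate across the junction; N-strand
    features are reverse-complemented.
    """
    L = len(genome)
    res = genome.seq.residues
    if feature.wraps:
        if not (0 <= feature.start <= L and 0 <= feature.end <= L):
            raise CoordinateError(f"{feature.name}: coordinates out of range")
        j_seq = res[feature.start:] + res[:feature.end]
    else:
        if not (0 <= feature.start < feature.end <= L):
            raise CoordinateError(f"{feature.name}: coordinates out of range")
        j_seq = res[feature.start:feature.end]
    return j_seq if feature.strand == "J" else revcomp(j_seq)
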