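"""Conservation profiling for structural RNAs.

Ribosomal RNA alignments are summarised column by column into three disjoint
classes: any gap makes a column an indel, otherwise identical residues make
it conserved and anything else a substitution — so the three counts always
sum to the alignment length.

Transfer RNAs are assessed against a cloverleaf secondary structure given as
a dot-bracket string: paired positions that fail to form a Watson–Crick (or,
optionally, G·U) pair are mismatches, attributed to the arm (acceptor, DHU,
anticodon, TψC) holding the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ARM_NAMES = ("acceptor", "DHU", "anticodon", "TpsiC", "extra")


@dataclass
class AlignmentProfile:
    n_columns: int
    conserved: int
    indel: int
    substitution: int

    def __post_init__(self) -> None:
        if self.conserved + self.indel + self.substitution != self.n_columns:
            raise ValueError("column classes do not sum to alignment length")

    @property
    def fractions(self) -> tuple[float, float, float]:
        n = self.n_columns
        return self.conserved / n, self.indel / n, self.substitution / n


@dataclass
class TrnaStructure:
    """A tRNA sequence with dot-bracket pairing and arm assignments.

    ``arms`` maps an arm name to a list of (start, end) position ranges it
    spans (both stem strands).  A pair is attributed to the arm containing
    its 5' position.
    """

    sequence: str
    pairing: str
    arms: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.pairing):
            raise ValueError("sequence and pairing strings differ in length")
        self.pairs  # validate balance

    @property
    def pairs(self) -> list[tuple[int, int]]:
        stack: list[int] = []
        out = []
        for i, ch in enumerate(self.pairing):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {i}")
                out.append((stack.pop(), i))
            elif ch != ".":
                raise ValueError(f"invalid pairing character {ch!r}")
        if stack:
            raise ValueError("unbalanced '(' in pairing string")
        return sorted(out)

    def arm_of(self, position: int) -> str:
        for arm, ranges in self.arms.items():
            for s, e in ranges:
                if s <= position < e:
                    return arm
        return "unassigned"


def classify_alignment_columns(alignment: list[str] | dict[str, str]
                               ) -> AlignmentProfile:
    """Classify every column of a gapped alignment as conserved/indel/substitution."""
    rows = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(rows) < 2:
        raise ValueError("need at least 2 sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment (unequal row lengths)")
    conserved = indel = substitution = 0
    rows = [r.upper() for r in rows]
    for j in range(width):
        column = [r[j] for r in rows]
        if any(ch in "-." for ch in column):
            indel += 1
        elif len(set(column)) == 1:
            conserved += 1
        else:
            substitution += 1
    return AlignmentProfile(n_columns=width, conserved=conserved,
                            indel=indel, substitution=substitution)


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def stem_mismatches(trna: TrnaStructure, allow_gu: bool = True
                    ) -> dict[str, int]:
    """Per-arm count of stem positions that fail to pair."""
    valid = _WC | _GU if allow_gu else _WC
    counts: dict[str, int] = {}
    seq = trna.sequence.upper()
    for i, j in trna.pairs:
        if (seq[i], seq[j]) not in valid:
            arm = trna.arm_of(i)
            counts[arm] = counts.get(arm, 0) + 1
    return counts


def detect_dhu_loss(trna: TrnaStructure) -> bool:
    """True when the DHU arm contains no paired positions (>= 1 pair keeps it)."""
    ranges = trna.arms.get("DHU", [])
    if not ranges:
        return True
    for i, j in trna.pairs:
        for s, e in ranges:
            if s <= i < e:
                return False
    return True
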