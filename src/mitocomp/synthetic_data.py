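"""Synthetic mitogenome and sequence-evolution generators.

These generators produce fixtures with the statistical structure the
analysis stages assume, so the whole pipeline is testable offline:

* :func:`generate_mitogenome` emits a circular genome in the ancestral
  arthropod gene order (13 PCGs, 22 tRNAs, 2 rRNAs, control region), with a
  configurable AT content (the generator solves for codon and filler base
  weights so the expected whole-genome AT matches the target), planted 7 bp
  ATGATAA overlaps at atp8–atp6 and nad4–nad4L, truncated T/TA stops before
  abutting tRNAs, intergenic spacers carrying tandem repeats, and a control
  region laid out as G+A-rich / C-rich / A+T-rich blocks, a stem-loop and a
  variable domain.  Every planted structure is returned as ground truth.

* :func:`simulate_cds_pair` evolves codon sequences at a chosen dN/dS
  (omega) under a reversible codon substitution process (synonymous changes
  at relative rate 1, nonsynonymous at rate omega, stop codons never
  visited), for Ka/Ks parameter-recovery experiments.

* :func:`generate_clade` evolves a root genome down a Newick tree, codon
  model on PCGs and Jukes–Cantor elsewhere, retaining the generating
  topology as ground truth.

All randomness flows from a single integer seed; no global random state is
touched.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import brentq
from skbio.tree import TreeNode

from . import genetic_code as gc
from .io import CircularSequence, GeneFeature, MitoGenome
from .rna_conservation import TrnaStructure

# --------------------------------------------------------------------------
# ancestral arthropod gene order (name, kind, strand); CR sits after rrnS

ANCESTRAL_GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("trnI", "tRNA", "J"), ("trnQ", "tRNA", "N"), ("trnM", "tRNA", "J"),
    ("nad2", "PCG", "J"), ("trnW", "tRNA", "J"), ("trnC", "tRNA", "N"),
    ("trnY", "tRNA", "N"), ("cox1", "PCG", "J"), ("trnL1", "tRNA", "J"),
    ("cox2", "PCG", "J"), ("trnK", "tRNA", "J"), ("trnD", "tRNA", "J"),
    ("atp8", "PCG", "J"), ("atp6", "PCG", "J"), ("cox3", "PCG", "J"),
    ("trnG", "tRNA", "J"), ("nad3", "PCG", "J"), ("trnA", "tRNA", "J"),
    ("trnR", "tRNA", "J"), ("trnN", "tRNA", "J"), ("trnS1", "tRNA", "J"),
    ("trnE", "tRNA", "J"), ("trnF", "tRNA", "N"), ("nad5", "PCG", "N"),
    ("trnH", "tRNA", "N"), ("nad4", "PCG", "N"), ("nad4L", "PCG", "N"),
    ("trnT", "tRNA", "J"), ("trnP", "tRNA", "N"), ("nad6", "PCG", "J"),
    ("cytb", "PCG", "J"), ("trnS2", "tRNA", "J"), ("nad1", "PCG", "N"),
    ("trnL2", "tRNA", "N"), ("rrnL", "rRNA", "N"), ("trnV", "tRNA", "N"),
    ("rrnS", "rRNA", "N"), ("CR", "CR", "J"),
)

# protein lengths in codons (start included, stop excluded), typical of
# heteropteran mitogenomes
PCG_CODONS = {
    "nad2": 324, "cox1": 512, "cox2": 227, "atp8": 53, "atp6": 224,
    "cox3": 261, "nad3": 117, "nad5": 573, "nad4": 446, "nad4L": 97,
    "nad6": 174, "cytb": 378, "nad1": 312,
}

RRNA_LENGTHS = {"rrnL": 1280, "rrnS": 800}

TRNA_ANTICODONS = {
    "trnI": "GAT", "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnC": "GCA",
    "trnY": "GTA", "trnL1": "TAA", "trnL2": "TAG", "trnK": "CTT", "trnD": "GTC",
    "trnG": "TCC", "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnS1": "GCT",
    "trnS2": "TGA", "trnE": "TTC", "trnF": "GAA", "trnH": "GTG", "trnT": "TGT",
    "trnP": "TGG", "trnV": "TAC",
}

# amino-acid frequencies typical of an AT-rich insect mitochondrial proteome
AA_FREQS = {
    "L": 0.145, "I": 0.105, "F": 0.085, "S": 0.105, "M": 0.060, "N": 0.050,
    "K": 0.045, "T": 0.050, "A": 0.040, "V": 0.050, "G": 0.055, "Y": 0.035,
    "W": 0.018, "P": 0.040, "H": 0.020, "Q": 0.022, "R": 0.020, "E": 0.025,
    "D": 0.020, "C": 0.010,
}

# genes ending on a truncated stop (remainder before an abutting tRNA)
TRUNCATED_STOPS = {"cox2": "T", "nad5": "TA"}

OVERLAP_MOTIF = "ATGATAA"


@dataclass
class RepeatSpec:
    unit_length: int = 60
    copies: float = 4.0
    divergence: float = 0.03


@dataclass
class CRSpec:
    ga_len: int = 60
    c_len: int = 40
    at_len: int = 80
    stem_len: int = 10
    loop_len: int = 8
    variable_len: int = 600
    repeat: RepeatSpec | None = None


@dataclass
class GenomeSpec:
    at_content: float = 0.75
    gene_order: tuple[tuple[str, str, str], ...] = ANCESTRAL_GENE_ORDER
    overlap_plantings: dict[tuple[str, str], str] = field(
        default_factory=lambda: {("atp8", "atp6"): OVERLAP_MOTIF,
                                 ("nad4", "nad4L"): OVERLAP_MOTIF})
    nc_plantings: dict[tuple[str, str], tuple[int, RepeatSpec | None]] = field(
        default_factory=lambda: {("trnI", "trnQ"): (400, RepeatSpec()),
                                 ("trnS2", "nad1"): (160, None)})
    cr: CRSpec = field(default_factory=CRSpec)
    codon_bias: float = 0.5  # Dirichlet concentration; small -> strong bias
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.at_content < 1:
            raise ValueError("at_content must be in (0, 1)")
        if self.codon_bias <= 0:
            raise ValueError("codon_bias must be positive")


@dataclass
class EvolSpec:
    omega: float = 0.2
    branch_length: float = 0.2  # expected substitutions per codon (pair total)
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.branch_length < 0:
            raise ValueError("branch_length must be non-negative")


@dataclass
class PlantedRepeat:
    location: tuple[str, str]  # flanking genes, or ("CR", "CR")
    start: int
    end: int
    unit_length: int
    copies: float


@dataclass
class GroundTruth:
    overlaps: dict[tuple[str, str], tuple[int, int, str]] = field(default_factory=dict)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    cr_span: tuple[int, int] | None = None
    cr_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    cr_stem_loop: tuple[int, int, int, int] | None = None  # start,end,stem,loop
    trna_structures: dict[str, TrnaStructure] = field(default_factory=dict)


# --------------------------------------------------------------------------
# base and codon sampling helpers


def _base_probs(at: float, at_skew: float = 0.0, gc_skew: float = 0.0
                ) -> np.ndarray:
    """(pA, pC, pG, pT) for target AT content and skews."""
    a = at / 2 * (1 + at_skew)
    t = at - a
    g = (1 - at) / 2 * (1 + gc_skew)
    c = (1 - at) - g
    return np.array([a, c, g, t])


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs / probs.sum())])


def _codon_probs_by_family(x: float, table_id: int = gc.DEFAULT_TABLE
                           ) -> dict[str, np.ndarray]:
    """Within-family codon probabilities from per-base AT weight x."""
    p = {"A": x / 2, "T": x / 2, "C": (1 - x) / 2, "G": (1 - x) / 2}
    out = {}
    for aa, codons in gc.synonymous_families(table_id).items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _expected_pcg_at(x: float, table_id: int = gc.DEFAULT_TABLE) -> float:
    """Expected AT fraction of coding sequence under the AA and codon models."""
    probs = _codon_probs_by_family(x, table_id)
    fams = gc.synonymous_families(table_id)
    at = 0.0
    for aa, f in AA_FREQS.items():
        codons = fams[aa]
        q = probs[aa]
        at += f * sum(qi * sum(1 for b in c if b in "AT") / 3
                      for qi, c in zip(q, codons))
    return at


def _solve_at_weight(target: float, pcg_nt: int, other_nt: int,
                     other_at: float) -> float:
    """AT weight x for codons so the length-weighted genome AT hits target."""
    needed = (target * (pcg_nt + other_nt) - other_at * other_nt) / pcg_nt

    def f(x: float) -> float:
        return _expected_pcg_at(x) - needed

    lo, hi = 0.02, 0.995
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-6)


def _tilt_to_at(fam_probs: dict[str, np.ndarray], target_at: float,
                table_id: int = gc.DEFAULT_TABLE) -> dict[str, np.ndarray]:
    """Exponentially tilt within-family codon probabilities to a coding-AT target.

    q_c is reweighted by w**(AT bases of c); w is solved so the expected AT
    over the amino-acid composition matches ``target_at`` (clipped to the
    achievable range).  Tilting preserves the concentration structure of the
    input distributions.
    """
    fams = gc.synonymous_families(table_id)
    at_counts = {aa: np.array([sum(1 for b in c if b in "AT") for c in fams[aa]])
                 for aa in fams}

    def expected_at(logw: float) -> float:
        w = np.exp(logw)
        at = 0.0
        for aa, f in AA_FREQS.items():
            q = fam_probs[aa] * np.power(w, at_counts[aa])
            q = q / q.sum()
            at += f * float(q @ at_counts[aa]) / 3.0
        return at

    lo, hi = -4.0, 4.0
    if expected_at(lo) >= target_at:
        logw = lo
    elif expected_at(hi) <= target_at:
        logw = hi
    else:
        logw = brentq(lambda v: expected_at(v) - target_at, lo, hi, xtol=1e-6)
    w = np.exp(logw)
    out = {}
    for aa, q in fam_probs.items():
        t = q * np.power(w, at_counts[aa])
        out[aa] = t / t.sum()
    return out


# --------------------------------------------------------------------------
# tRNA cloverleaf builder


def _build_trna(rng: np.random.Generator, name: str, fill: np.ndarray
                ) -> tuple[str, TrnaStructure]:
    """Random cloverleaf with exact-complement stems; trnS1 lacks the D stem."""
    anticodon = TRNA_ANTICODONS.get(name, "NNN").replace("N", "A")

    def stem_arm(n: int) -> str:
        # avoid N; ensure pairable bases only
        return _random_seq(rng, n, fill)

    acc = stem_arm(7)
    d5 = stem_arm(4)
    dloop = _random_seq(rng, 5, fill)
    ac5 = stem_arm(5)
    acloop = _random_seq(rng, 2, fill) + anticodon + _random_seq(rng, 2, fill)
    t5 = stem_arm(5)
    tloop = _random_seq(rng, 7, fill)
    var = _random_seq(rng, 4, fill)
    link1 = _random_seq(rng, 2, fill)
    link2 = _random_seq(rng, 1, fill)
    disc = _random_seq(rng, 1, fill)

    has_d_stem = name != "trnS1"
    parts: list[tuple[str, str, str]] = []  # (segment, bracket, arm)
    parts.append((acc, "(" * 7, "acceptor"))
    parts.append((link1, ".." , ""))
    if has_d_stem:
        parts.append((d5, "((((", "DHU"))
        parts.append((dloop, "." * 5, ""))
        parts.append((gc.revcomp(d5), "))))", "DHU"))
    else:
        parts.append((dloop + d5, "." * 9, ""))  # unpaired D-replacement loop
    parts.append((link2, ".", ""))
    parts.append((ac5, "(((((", "anticodon"))
    parts.append((acloop, "." * 7, ""))
    parts.append((gc.revcomp(ac5), ")))))", "anticodon"))
    parts.append((var, "." * 4, "extra"))
    parts.append((t5, "(((((", "TpsiC"))
    parts.append((tloop, "." * 7, ""))
    parts.append((gc.revcomp(t5), ")))))", "TpsiC"))
    parts.append((gc.revcomp(acc), ")" * 7, "acceptor"))
    parts.append((disc, ".", ""))

    seq = []
    brackets = []
    arms: dict[str, list[tuple[int, int]]] = {}
    pos = 0
    for segment, br, arm in parts:
        seq.append(segment)
        brackets.append(br)
        if arm:
            arms.setdefault(arm, []).append((pos, pos + len(segment)))
        pos += len(segment)
    structure = TrnaStructure(sequence="".join(seq), pairing="".join(brackets),
                              arms=arms)
    return structure.sequence, structure


# --------------------------------------------------------------------------
# PCG builder


def _sample_cds(rng: np.random.Generator, name: str, n_codons: int,
                fam_probs: dict[str, np.ndarray],
                table_id: int = gc.DEFAULT_TABLE) -> str:
    """Sense-codon sequence for one gene: start codon + sampled codons + stop.

    Genes with a planted truncated stop end on T/TA instead of a full stop.
    The atp8/nad4L tails and atp6/nad4 heads are fixed so that the planted
    ATGATAA overlaps are consistent on the shared strand.
    """
    fams = gc.synonymous_families(table_id)
    aas = list(AA_FREQS)
    aa_p = np.array([AA_FREQS[a] for a in aas])
    aa_p = aa_p / aa_p.sum()

    start = "TTG" if name == "cox1" else "ATG"
    body_codons: list[str] = []
    for aa in rng.choice(aas, size=n_codons - 1, p=aa_p):
        codons = fams[aa]
        body_codons.append(codons[rng.choice(len(codons), p=fam_probs[aa])])
    cds = start + "".join(body_codons)

    if name in ("atp8", "nad4L"):
        # last 9 nt = xxA TGA TAA so the final 7 read ATGATAA (stop included)
        cds = cds[:-6] + "GCA" + "TGA"
        cds += "TAA"
    elif name in ("atp6", "nad4"):
        # first 9 nt = ATG ATA ATT so the leading 7 read ATGATAA
        cds = "ATGATAATT" + cds[9:]
        cds += TRUNCATED_STOPS.get(name, "TAA")
    elif name in TRUNCATED_STOPS:
        cds += TRUNCATED_STOPS[name]
    else:
        cds += "TAA"
    return cds


# --------------------------------------------------------------------------
# repeats and control region


def _build_repeat(rng: np.random.Generator, spec: RepeatSpec,
                  fill: np.ndarray) -> tuple[str, int, float]:
    unit = _random_seq(rng, spec.unit_length, fill)
    full = int(spec.copies)
    frac_len = int(round((spec.copies - full) * spec.unit_length))
    copies = []
    for _ in range(full):
        copy = list(unit)
        for i in range(len(copy)):
            if rng.random() < spec.divergence:
                copy[i] = str(rng.choice([b for b in "ACGT" if b != copy[i]]))
        copies.append("".join(copy))
    seq = "".join(copies) + unit[:frac_len]
    return seq, spec.unit_length, len(seq) / spec.unit_length


def plant_tandem_repeat(rng: np.random.Generator,
                        unit_range: tuple[int, int] = (20, 100),
                        copies_range: tuple[float, float] = (2.5, 6.0),
                        divergence: float = 0.05,
                        flank: int = 100,
                        min_realized_identity: float | None = 0.9
                        ) -> tuple[str, int, float, float]:
    """A random tandem-repeat planting inside random flanks.

    Returns (sequence, unit length, true copies, realized identity), where
    realized identity is the measured fraction of positions matching at a
    lag of one unit across the planted array.  When
    ``min_realized_identity`` is set, plantings whose sampled mutations
    leave less identity than that are redrawn, so the planting satisfies
    the stated condition rather than only its expectation.
    """
    fill = _base_probs(0.72)
    while True:
        unit = int(rng.integers(unit_range[0], unit_range[1] + 1))
        copies = float(rng.uniform(*copies_range))
        rep, _, true_copies = _build_repeat(
            rng, RepeatSpec(unit, copies, divergence), fill)
        identity = float(np.mean([rep[i] == rep[i + unit]
                                  for i in range(len(rep) - unit)]))
        if min_realized_identity is None or identity >= min_realized_identity:
            seq = (_random_seq(rng, flank, fill) + rep
                   + _random_seq(rng, flank, fill))
            return seq, unit, true_copies, identity


def _build_cr(rng: np.random.Generator, spec: CRSpec, fill_at: float
              ) -> tuple[str, dict[str, tuple[int, int]],
                         tuple[int, int, int, int], list[tuple[int, int, int, float]]]:
    """Control region string plus block/stem-loop/repeat coordinates (CR-local)."""
    pieces: list[str] = []
    pos = 0
    blocks: dict[str, tuple[int, int]] = {}

    ga = _random_seq(rng, spec.ga_len, np.array([0.70, 0.02, 0.26, 0.02]))
    blocks["GA"] = (pos, pos + len(ga))
    pieces.append(ga)
    pos += len(ga)

    c = _random_seq(rng, spec.c_len, np.array([0.10, 0.78, 0.02, 0.10]))
    blocks["C"] = (pos, pos + len(c))
    pieces.append(c)
    pos += len(c)

    at = _random_seq(rng, spec.at_len, np.array([0.49, 0.01, 0.01, 0.49]))
    blocks["AT"] = (pos, pos + len(at))
    pieces.append(at)
    pos += len(at)

    arm = _random_seq(rng, spec.stem_len, np.array([0.15, 0.35, 0.35, 0.15]))
    loop = _random_seq(rng, spec.loop_len, _base_probs(0.9))
    hairpin = arm + loop + gc.revcomp(arm)
    stem_loop = (pos, pos + len(hairpin), spec.stem_len, spec.loop_len)
    pieces.append(hairpin)
    pos += len(hairpin)

    repeats: list[tuple[int, int, int, float]] = []
    var_fill = _base_probs(min(fill_at, 0.80), at_skew=0.05)
    if spec.repeat is not None:
        pad = _random_seq(rng, 30, var_fill)
        pieces.append(pad)
        pos += len(pad)
        rep, unit, copies = _build_repeat(rng, spec.repeat, _base_probs(0.70))
        repeats.append((pos, pos + len(rep), unit, copies))
        pieces.append(rep)
        pos += len(rep)
        rest = max(spec.variable_len - len(rep) - 30, 30)
    else:
        rest = spec.variable_len
    pieces.append(_random_seq(rng, rest, var_fill))
    pos += rest
    return "".join(pieces), blocks, stem_loop, repeats


def generate_control_region(spec: CRSpec, seed: int
                            ) -> tuple[str, dict[str, tuple[int, int]],
                                       tuple[int, int, int, int],
                                       list[tuple[int, int, int, float]]]:
    """A standalone control-region fixture with planted ground truth.

    Returns (sequence, block coordinates, stem-loop (start, end, stem, loop),
    repeat plantings) with all coordinates local to the sequence, position 0
    at the rrnS-proximal end.
    """
    rng = np.random.default_rng(seed)
    return _build_cr(rng, spec, 0.85)


# --------------------------------------------------------------------------
# genome assembly


def generate_mitogenome(spec: GenomeSpec) -> tuple[MitoGenome, GroundTruth]:
    """Deterministic synthetic mitogenome plus planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    table_id = 5

    pcg_nt = sum(3 * (n + 1) for n in PCG_CODONS.values())
    fill_at = 0.93  # AT of tRNA/rRNA/spacer filler sequence
    # expected AT budget of every non-PCG part, so the codon-model AT weight
    # can be solved to hit the whole-genome target exactly in expectation
    other_parts: list[tuple[int, float]] = [
        (22 * 69, fill_at), (sum(RRNA_LENGTHS.values()), fill_at),
        (spec.cr.ga_len, 0.72), (spec.cr.c_len, 0.20), (spec.cr.at_len, 0.98),
        (2 * spec.cr.stem_len, 0.30), (spec.cr.loop_len, 0.90),
    ]
    if spec.cr.repeat is not None:
        rep_len = int(spec.cr.repeat.unit_length * spec.cr.repeat.copies)
        other_parts += [(30, 0.80), (rep_len, 0.70),
                        (max(spec.cr.variable_len - rep_len - 30, 30), 0.80)]
    else:
        other_parts.append((spec.cr.variable_len, 0.80))
    for length, repspec in spec.nc_plantings.values():
        if repspec is None:
            other_parts.append((length, fill_at))
        else:
            rep_len = int(repspec.unit_length * repspec.copies)
            flank = max((length - rep_len) // 2, 10)
            other_parts += [(2 * flank, fill_at), (rep_len, 0.72)]
    other_nt = sum(n for n, _ in other_parts)
    other_at = sum(n * a for n, a in other_parts) / other_nt
    x = _solve_at_weight(spec.at_content, pcg_nt, other_nt, other_at)
    base_fam_probs = _codon_probs_by_family(x, table_id)
    # per-genome Dirichlet draw concentrates usage within families
    fam_probs = {}
    for aa, q in base_fam_probs.items():
        alpha = spec.codon_bias * len(q) * q + 1e-6
        fam_probs[aa] = rng.dirichlet(alpha)
    # the single Dirichlet draw shifts the genome's expected AT; tilt the
    # drawn probabilities back so the coding AT matches the solved budget
    needed = (spec.at_content * (pcg_nt + other_nt) - other_at * other_nt) / pcg_nt
    fam_probs = _tilt_to_at(fam_probs, needed, table_id)
    rna_fill = _base_probs(other_at, at_skew=0.04, gc_skew=0.10)

    truth = GroundTruth()
    order = spec.gene_order
    features: list[GeneFeature] = []
    cursor = 0
    prev_name = None
    genome_chars: list[str] = []

    def write(seq_j: str, start: int) -> None:
        need = start + len(seq_j)
        while len(genome_chars) < need:
            genome_chars.append("")
        genome_chars[start:need] = list(seq_j)

    for name, kind, strand in order:
        # spacer before this gene (planted NC or small random gap)
        planted_nc = spec.nc_plantings.get((prev_name, name)) if prev_name else None
        overlap = spec.overlap_plantings.get((prev_name, name)) if prev_name else None
        if planted_nc is not None:
            length, repspec = planted_nc
            if repspec is not None:
                flank = max((length - int(repspec.unit_length * repspec.copies)) // 2,
                            10)
                left = _random_seq(rng, flank, rna_fill)
                rep, unit, copies = _build_repeat(rng, repspec, _base_probs(0.72))
                right = _random_seq(rng, flank, rna_fill)
                write(left, cursor)
                cursor += len(left)
                truth.repeats.append(PlantedRepeat(
                    location=(prev_name, name), start=cursor,
                    end=cursor + len(rep), unit_length=unit, copies=copies))
                write(rep, cursor)
                cursor += len(rep)
                write(right, cursor)
                cursor += len(right)
            else:
                nc = _random_seq(rng, length, rna_fill)
                write(nc, cursor)
                cursor += length
        elif overlap is None and prev_name is not None:
            # truncated-stop junctions and their N-strand mirrors need 0 gap;
            # give every other junction a small random spacer
            zero_gap = (prev_name in TRUNCATED_STOPS
                        or name in TRUNCATED_STOPS
                        or prev_name in ("trnF", "trnH")
                        or kind == "CR")  # CR abuts rrnS
            gap = 0 if zero_gap else int(rng.integers(0, 4))
            if gap:
                write(_random_seq(rng, gap, rna_fill), cursor)
                cursor += gap

        if kind == "PCG":
            cds = _sample_cds(rng, name, PCG_CODONS[name], fam_probs, table_id)
            seq_j = cds if strand == "J" else gc.revcomp(cds)
        elif kind == "tRNA":
            coding, structure = _build_trna(rng, name, rna_fill)
            truth.trna_structures[name] = structure
            seq_j = coding if strand == "J" else gc.revcomp(coding)
        elif kind == "rRNA":
            coding = _random_seq(rng, RRNA_LENGTHS[name], rna_fill)
            seq_j = coding if strand == "J" else gc.revcomp(coding)
        elif kind == "CR":
            cr_seq, blocks, stem_loop, cr_repeats = _build_cr(
                rng, spec.cr, spec.at_content + 0.10)
            # CR string is built rrnS-proximal-first; here rrnS precedes the
            # CR on the J-strand, so position 0 of the CR is already the
            # rrnS-proximal end and no flip is needed
            seq_j = cr_seq
        else:
            raise ValueError(f"unknown kind {kind} in gene order")

        start = cursor
        if overlap is not None:
            L_ov = len(overlap)
            start = cursor - L_ov
            prev_tail = "".join(genome_chars[start:cursor])
            # the J-strand head of this gene must equal the previous gene's
            # J-strand tail across the shared region (for an N-strand pair
            # both are the reverse complement of the coding-strand motif)
            head = seq_j[:L_ov]
            expected_j = overlap if strand == "J" else gc.revcomp(overlap)
            if prev_tail != head or head != expected_j:
                raise ValueError(
                    f"infeasible overlap planting {prev_name}-{name}: "
                    f"constructed {prev_tail}/{head}, requested {expected_j}")
            truth.overlaps[(prev_name, name)] = (
                start, cursor, overlap)
        write(seq_j, start)
        end = start + len(seq_j)
        cursor = max(cursor, end)
        features.append(GeneFeature(name=name, kind=kind, strand=strand,
                                    start=start, end=end,
                                    anticodon=TRNA_ANTICODONS.get(name)))
        if kind == "CR":
            truth.cr_span = (start, end)
            truth.cr_blocks = {k: (s + start, e + start)
                               for k, (s, e) in blocks.items()}
            sl = stem_loop
            truth.cr_stem_loop = (sl[0] + start, sl[1] + start, sl[2], sl[3])
            for rs, re_, unit, copies in cr_repeats:
                truth.repeats.append(PlantedRepeat(
                    location=("CR", "CR"), start=rs + start, end=re_ + start,
                    unit_length=unit, copies=copies))
        prev_name = name

    residues = "".join(genome_chars)
    genome = MitoGenome(id=f"synthetic-{spec.seed}",
                        seq=CircularSequence(residues),
                        features=features, transl_table=table_id)
    _check_no_internal_stops(genome)
    return genome, truth


def _check_no_internal_stops(genome: MitoGenome) -> None:
    from .io import feature_sequence
    stops = gc.stop_codons(genome.transl_table)
    for f in genome.genes("PCG"):
        cds = feature_sequence(genome, f)
        usable = len(cds) - len(cds) % 3
        codons = [cds[i:i + 3] for i in range(0, usable - 3, 3)]
        bad = [i for i, c in enumerate(codons) if c in stops]
        if bad:
            raise AssertionError(f"{f.name}: internal stop at codon {bad[0]}")


# --------------------------------------------------------------------------
# codon-evolution simulator


def _codon_model(omega: float, kappa: float = 1.0,
                 table_id: int = gc.DEFAULT_TABLE):
    """Symmetric codon rate matrix (unit mean rate) and its eigensystem."""
    sense = gc.sense_codons(table_id)
    idx = {c: i for i, c in enumerate(sense)}
    trans = gc.translation(table_id)
    n = len(sense)
    Q = np.zeros((n, n))
    for a in sense:
        for pos in range(3):
            for b in "ACGT":
                if b == a[pos]:
                    continue
                m = a[:pos] + b + a[pos + 1:]
                if m not in idx:
                    continue
                rate = kappa if (a[pos], b) in (("A", "G"), ("G", "A"),
                                                ("C", "T"), ("T", "C")) else 1.0
                if trans[a] != trans[m]:
                    rate *= omega
                Q[idx[a], idx[m]] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    Q /= mean_rate
    vals, vecs = eigh(Q)
    return sense, vals, vecs


def _transition_matrix(vals: np.ndarray, vecs: np.ndarray, t: float) -> np.ndarray:
    P = vecs @ np.diag(np.exp(vals * t)) @ vecs.T
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _evolve_states(rng: np.random.Generator, states: np.ndarray,
                   P: np.ndarray) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(states.size)
    rows = cum[states]
    return (u[:, None] > rows).sum(axis=1).astype(np.int64)


def simulate_cds_pair(ancestral_len: int, spec: EvolSpec
                      ) -> tuple[str, str]:
    """Two codon sequences diverged by ``branch_length`` substitutions/codon.

    The ancestor is uniform over sense codons; each descendant evolves for
    half the branch length under the omega-scaled codon process, so the pair
    divergence equals the spec's branch length in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    sense, vals, vecs = _codon_model(spec.omega, spec.kappa)
    anc = rng.integers(0, len(sense), size=ancestral_len)
    if spec.branch_length == 0:
        seq = "".join(sense[i] for i in anc)
        return seq, seq
    P = _transition_matrix(vals, vecs, spec.branch_length / 2.0)
    a = _evolve_states(rng, anc, P)
    b = _evolve_states(rng, anc, P)
    return ("".join(sense[i] for i in a), "".join(sense[i] for i in b))


# --------------------------------------------------------------------------
# clade simulator


def generate_clade(tree_newick: str, spec: EvolSpec, root: MitoGenome
                   ) -> dict[str, MitoGenome]:
    """Evolve a root genome down a Newick tree; returns {tip name: genome}.

    PCG codons evolve under the omega-scaled codon model, everything else
    under Jukes–Cantor; Newick branch lengths are expected substitutions per
    nucleotide site (codon branch lengths are three times that).  Positions
    inside overlapping PCGs are owned by the first gene in genome order.
    """
    tree = TreeNode.read(_io.StringIO(tree_newick))
    rng = np.random.default_rng(spec.seed)
    sense, vals, vecs = _codon_model(spec.omega, spec.kappa)
    codon_idx = {c: i for i, c in enumerate(sense)}

    L = len(root)
    owner = np.full(L, -1, dtype=np.int64)  # PCG index owning each position
    pcgs = [f for f in root.features if f.kind == "PCG"]
    for k, f in enumerate(pcgs):
        span = (list(range(f.start, L)) + list(range(f.end)) if f.wraps
                else list(range(f.start, f.end)))
        for p in span:
            if owner[p] == -1:
                owner[p] = k

    base_idx = {b: i for i, b in enumerate("ACGT")}

    def evolve_seq(seq: str, t: float) -> str:
        if t <= 0:
            return seq
        chars = np.array(list(seq))
        # Jukes-Cantor on non-PCG positions
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        jc_mask = owner < 0
        hits = rng.random(L) < p_change
        for pos in np.flatnonzero(jc_mask & hits):
            cur = chars[pos]
            if cur not in base_idx:
                continue
            chars[pos] = rng.choice([b for b in "ACGT" if b != cur])
        # codon model per PCG
        P = _transition_matrix(vals, vecs, 3.0 * t)
        for k, f in enumerate(pcgs):
            from .io import feature_sequence as fs
            tmp = MitoGenome(id="tmp", seq=CircularSequence("".join(chars)),
                             features=[f], transl_table=root.transl_table)
            cds = fs(tmp, f)
            usable = len(cds) - len(cds) % 3
            states = []
            positions = []
            for i in range(0, usable, 3):
                c = cds[i:i + 3]
                if c in codon_idx:
                    states.append(codon_idx[c])
                    positions.append(i)
            if not states:
                continue
            new_states = _evolve_states(rng, np.array(states), P)
            cds_list = list(cds)
            for i, st in zip(positions, new_states):
                cds_list[i:i + 3] = sense[st]
            new_cds = "".join(cds_list)
            j_seq = new_cds if f.strand == "J" else gc.revcomp(new_cds)
            # write back only owned positions
            span = (list(range(f.start, L)) + list(range(f.end)) if f.wraps
                    else list(range(f.start, f.end)))
            for offset, p in enumerate(span):
                if owner[p] == k:
                    chars[p] = j_seq[offset]
        return "".join(chars)

    results: dict[str, MitoGenome] = {}
    seqs = {id(tree): root.seq.residues}
    for node in tree.preorder(include_self=True):
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        t = node.length or 0.0
        child_seq = evolve_seq(parent_seq, t)
        seqs[id(node)] = child_seq
        if node.is_tip():
            results[node.name] = MitoGenome(
                id=node.name, seq=CircularSequence(child_seq),
                features=[GeneFeature(f.name, f.kind, f.strand, f.start,
                                      f.end, f.wraps, f.anticodon)
                          for f in root.features],
                transl_table=root.transl_table)
    return results
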