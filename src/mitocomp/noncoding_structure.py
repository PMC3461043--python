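"""Structure of non-coding mitogenome regions.

Three detectors:

* a period-scan tandem-repeat finder (unit length, copy number, identity,
  consensus) for the repeat arrays that inflate intergenic spacers and the
  control region;
* a sliding-window composition segmenter for the control region's conserved
  blocks — a G+A-rich block at the rrnS-proximal (3') end, a C-rich block
  upstream of it, and an A+T-rich block upstream of that, with the remainder
  forming the variable domain;
* an inverted-repeat scanner for stem-loop (hairpin) structures, optionally
  admitting G·U pairs and a bounded number of internal mismatches.

Control-region sequences are expected on the J-strand with position 0 at the
rrnS-proximal end, which is their natural orientation when extracted from a
genome in the ancestral arthropod gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# calibration defaults for block segmentation (window in bp, thresholds as
# window composition fractions)
BLOCK_WINDOW = 20
GA_THRESHOLD = 0.80
C_THRESHOLD = 0.60
AT_THRESHOLD = 0.90


@dataclass
class TandemRepeat:
    start: int
    end: int
    unit_length: int
    copies: float
    span: int
    identity: float
    consensus: str

    def __post_init__(self) -> None:
        if abs(self.span - self.unit_length * self.copies) > self.unit_length:
            raise ValueError("span inconsistent with unit_length * copies")


@dataclass
class StemLoop:
    start: int
    end: int
    stem_len: int
    loop_len: int
    pairs: int       # paired stem positions
    mismatches: int  # stem positions that do not pair


@dataclass
class CompositionBlock:
    kind: str  # "GA", "C" or "AT"
    start: int
    end: int
    fraction: float  # composition of the block in its defining bases


@dataclass
class CRAnnotation:
    ga_block: CompositionBlock | None = None
    c_block: CompositionBlock | None = None
    at_block: CompositionBlock | None = None
    stem_loops: list[StemLoop] = field(default_factory=list)
    variable_domain: tuple[int, int] | None = None


# --------------------------------------------------------------------------
# tandem repeats


def find_tandem_repeats(seq: str, min_unit: int = 10, max_unit: int = 200,
                        min_copies: float = 2.0,
                        min_identity: float = 0.8) -> list[TandemRepeat]:
    """Period-scan tandem repeat detection.

    For each candidate period p, positions where seq[i] == seq[i+p] are
    scored; maximal runs whose per-unit identity exceeds ``min_identity``
    become candidate arrays with copies = span / p.  Overlapping candidates
    are resolved by span, then identity, then smaller unit.
    """
    s = seq.upper()
    L = len(s)
    if L < 2 * min_unit:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[TandemRepeat] = []
    for p in range(min_unit, min(max_unit, L // 2) + 1):
        match = (arr[:-p] == arr[p:]).astype(np.float64)
        if match.size < p:
            continue
        # identity of the unit starting at i versus the next copy
        kernel = np.ones(p) / p
        unit_id = np.convolve(match, kernel, mode="valid")  # length L-2p+1
        above = unit_id >= min_identity
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        # a locally divergent stretch knocks out up to a unit's worth of
        # windows; gaps shorter than one period stay in the same array
        splits = np.flatnonzero(np.diff(idx) > p)
        run_starts = np.concatenate(([0], splits + 1))
        run_ends = np.concatenate((splits, [idx.size - 1]))
        for rs, re in zip(run_starts, run_ends):
            a = int(idx[rs])
            b = int(idx[re])  # last window start with good identity
            start = a
            end = min(b + 2 * p, L)  # window b covers seq[b : b+2p]
            # edge windows blend array and flank; trim each edge until a
            # short runway of positions reaches the identity threshold
            w = min(5, p)
            while (start < end - p
                   and match[start:start + w].mean() < min_identity):
                start += 1
            while (end - p - w >= start
                   and match[end - p - w:end - p].mean() < min_identity):
                end -= 1
            span = end - start
            copies = span / p
            if copies < min_copies:
                continue
            identity = float(match[start:end - p].mean())
            candidates.append(TandemRepeat(
                start=start, end=end, unit_length=p, copies=round(copies, 2),
                span=span, identity=identity,
                consensus=_consensus_unit(s, start, end, p)))
    return _resolve_overlaps(candidates)


def _consensus_unit(s: str, start: int, end: int, p: int) -> str:
    full = (end - start) // p
    if full < 1:
        return s[start:start + p]
    cols = []
    for j in range(p):
        votes: dict[str, int] = {}
        for c in range(full):
            ch = s[start + c * p + j]
            votes[ch] = votes.get(ch, 0) + 1
        cols.append(max(sorted(votes), key=votes.get))
    return "".join(cols)


def _resolve_overlaps(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    # An array of period p also scores at periods 2p, 3p, ... with comparable
    # identity; such harmonic calls are dropped in favour of the fundamental
    # period before the remaining candidates are accepted greedily by span,
    # then identity.
    def is_harmonic(c: TandemRepeat) -> bool:
        for d in candidates:
            if d is c or d.unit_length >= c.unit_length:
                continue
            ov = min(c.end, d.end) - max(c.start, d.start)
            if ov < 0.6 * c.span:  # the fundamental call covers the array
                continue
            k = round(c.unit_length / d.unit_length)
            if (k >= 2 and abs(c.unit_length - k * d.unit_length) <= 2
                    and d.identity >= c.identity - 0.1):
                return True
        return False

    ranked = sorted((c for c in candidates if not is_harmonic(c)),
                    key=lambda r: (-r.span, -r.identity, r.unit_length))
    chosen: list[TandemRepeat] = []
    for cand in ranked:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


# --------------------------------------------------------------------------
# control-region composition blocks


def _block_candidates(s: str, bases: str, threshold: float,
                      window: int) -> list[CompositionBlock]:
    L = len(s)
    if L < window:
        raise ValueError("sequence shorter than window")
    ind = np.array([1.0 if ch in bases else 0.0 for ch in s])
    roll = np.convolve(ind, np.ones(window) / window, mode="valid")
    above = roll >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # windows separated by less than one window still describe the same
    # block (a single sub-threshold window should not split it)
    splits = np.flatnonzero(np.diff(idx) > window)
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [idx.size - 1]))
    blocks = []
    for a, b in zip(starts, ends):
        s0 = int(idx[a])
        e0 = int(idx[b]) + window
        frac = float(ind[s0:e0].mean())
        blocks.append(CompositionBlock(kind=bases, start=s0, end=e0, fraction=frac))
    return blocks


def _best_block(blocks: list[CompositionBlock],
                threshold: float) -> CompositionBlock | None:
    if not blocks:
        return None
    return max(blocks, key=lambda b: (b.fraction - threshold) * (b.end - b.start))


def find_composition_blocks(cr_seq: str, window: int = BLOCK_WINDOW,
                            ga_threshold: float = GA_THRESHOLD,
                            c_threshold: float = C_THRESHOLD,
                            at_threshold: float = AT_THRESHOLD) -> CRAnnotation:
    """Locate the conserved G+A-rich, C-rich and A+T-rich blocks of a CR.

    The G+A block is searched from the rrnS-proximal end (position 0) first;
    the C-rich block is the first qualifying run upstream (after) it, and the
    A+T-rich block the first qualifying run after the C block — mirroring the
    canonical block layout.  An A+T-rich background makes spurious AT windows
    common, so when no C block anchors the search the A+T block falls back to
    the best-scoring run (excess composition × length).
    """
    s = cr_seq.upper()
    ga_runs = _block_candidates(s, "GA", ga_threshold, window)
    ga = min(ga_runs, key=lambda b: b.start) if ga_runs else None

    def first_after(runs: list[CompositionBlock],
                    prev: CompositionBlock | None) -> CompositionBlock | None:
        # a run may start up to a window inside the previous block (its edge
        # windows blend the two compositions); the overlap is clamped later
        if prev is not None:
            runs = [b for b in runs
                    if b.end > prev.end and b.start >= prev.end - window]
        return min(runs, key=lambda b: b.start) if runs else None

    c = first_after(_block_candidates(s, "C", c_threshold, window), ga)

    at_runs = _block_candidates(s, "AT", at_threshold, window)
    if c is not None or ga is not None:
        at = first_after(at_runs, c if c is not None else ga)
    else:
        at = _best_block(at_runs, at_threshold)

    # enforce non-overlap in layout order
    blocks = [b for b in (ga, c, at) if b is not None]
    for earlier, later in zip(blocks, blocks[1:]):
        if later.start < earlier.end:
            later.start = earlier.end
    last_end = max((b.end for b in blocks), default=0)
    variable = (last_end, len(s)) if last_end < len(s) else None
    return CRAnnotation(ga_block=ga, c_block=c, at_block=at,
                        variable_domain=variable)


# --------------------------------------------------------------------------
# stem-loops

_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _pair_matrix(allow_gu: bool) -> np.ndarray:
    m = np.zeros((5, 5), dtype=bool)
    pairs = [(0, 3), (1, 2)]  # A-T, C-G
    if allow_gu:
        pairs.append((2, 3))  # G-T (G.U in the transcript)
    for i, j in pairs:
        m[i, j] = m[j, i] = True
    return m


def find_stem_loops(seq: str, min_stem: int = 6,
                    loop_range: tuple[int, int] = (3, 20),
                    allow_gu: bool = True, max_mismatch: int = 1,
                    max_stem: int = 30) -> list[StemLoop]:
    """Scan for inverted repeats forming hairpins.

    A candidate has two stem arms of equal length >= ``min_stem`` whose
    positions pair (Watson–Crick, plus G·U when allowed) except for at most
    ``max_mismatch`` internal positions; both terminal stem pairs must pair.
    Candidates are ranked by stem length, then fewest mismatches, and
    accepted greedily without overlap.
    """
    s = seq.upper()
    L = len(s)
    if L == 0:
        return []
    codes = np.array([_CODE.get(b, 4) for b in s.encode()], dtype=np.int8)
    pm = _pair_matrix(allow_gu)
    lo, hi = loop_range
    candidates: list[StemLoop] = []
    for stem in range(min(max_stem, (L - lo) // 2), min_stem - 1, -1):
        for loop in range(lo, hi + 1):
            total = 2 * stem + loop
            if total > L:
                continue
            n_start = L - total + 1
            paired = np.zeros((n_start, stem), dtype=bool)
            for j in range(stem):
                left = codes[j:j + n_start]
                right = codes[total - 1 - j:total - 1 - j + n_start]
                paired[:, j] = pm[left, right]
            n_paired = paired.sum(axis=1)
            ok = (n_paired >= stem - max_mismatch) & paired[:, 0] & paired[:, -1]
            for i in np.flatnonzero(ok):
                candidates.append(StemLoop(
                    start=int(i), end=int(i) + total, stem_len=stem,
                    loop_len=loop, pairs=int(n_paired[i]),
                    mismatches=stem - int(n_paired[i])))
    ranked = sorted(candidates,
                    key=lambda h: (-h.stem_len, h.mismatches, h.start))
    chosen: list[StemLoop] = []
    for cand in ranked:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda h: h.start)
    return chosen


def annotate_control_region(cr_seq: str, window: int = BLOCK_WINDOW,
                            min_stem: int = 6,
                            loop_range: tuple[int, int] = (3, 20),
                            allow_gu: bool = True,
                            max_mismatch: int = 1) -> CRAnnotation:
    """Full CR annotation: composition blocks plus stem-loops.

    Stem-loops are searched downstream of the last composition block (the
    region toward the variable domain), falling back to the whole sequence
    when no blocks are found.
    """
    ann = find_composition_blocks(cr_seq, window=window)
    blocks_end = max((b.end for b in (ann.ga_block, ann.c_block, ann.at_block)
                      if b is not None), default=0)
    # detected block edges can overrun a directly abutting hairpin by a few
    # positions, so back the search region up by one window
    offset = max(0, blocks_end - window)
    region = cr_seq[offset:]
    hairpins = find_stem_loops(region, min_stem=min_stem,
                               loop_range=loop_range, allow_gu=allow_gu,
                               max_mismatch=max_mismatch)
    ann.stem_loops = [StemLoop(start=h.start + offset,
                               end=h.end + offset, stem_len=h.stem_len,
                               loop_len=h.loop_len, pairs=h.pairs,
                               mismatches=h.mismatches) for h in hairpins]
    if ann.stem_loops:
        first_sl = min(h.end for h in ann.stem_loops)
        ann.variable_domain = (max(blocks_end, first_sl), len(cr_seq))
    return ann
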