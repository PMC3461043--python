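"""Concatenated supermatrix and distance-based (neighbor-joining) trees.

This is the desk-scale phylogenetic stage: per-gene alignments are
concatenated into a partitioned supermatrix, pairwise distances are computed
under the p-distance or Kimura two-parameter model with pairwise deletion of
gapped columns, and a Saitou–Nei neighbor-joining tree (via scikit-bio) is
rooted on an outgroup.  It serves as a surrogate for full ML/Bayesian
inference, which is deliberately out of scope.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class Supermatrix:
    taxa: list[str]
    partitions: dict[str, tuple[int, int]]  # gene -> [start, end) columns
    matrix: dict[str, str]  # taxon -> concatenated row

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.matrix.values()}
        if len(widths) > 1:
            raise ValueError("supermatrix rows differ in length")
        width = widths.pop() if widths else 0
        spans = sorted(self.partitions.values())
        pos = 0
        for s, e in spans:
            if s != pos:
                raise ValueError("partition ranges do not tile the columns")
            pos = e
        if spans and pos != width:
            raise ValueError("partition ranges do not cover the matrix width")

    @property
    def width(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal; NaN marks missing

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.d - self.d.T)) > 1e-9:
                raise ValueError("matrix must be symmetric")


def concatenate_supermatrix(per_gene_alignments: dict[str, dict[str, str]],
                            exclude: set[str] | frozenset[str] = frozenset()
                            ) -> Supermatrix:
    """Concatenate per-gene alignments; missing taxa are gap-filled."""
    genes = [g for g in per_gene_alignments if g not in exclude]
    if not genes:
        raise ValueError("no genes to concatenate")
    taxa = sorted({t for g in genes for t in per_gene_alignments[g]})
    partitions: dict[str, tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    pos = 0
    for gene in genes:
        aln = per_gene_alignments[gene]
        widths = {len(s) for s in aln.values()}
        if len(widths) != 1:
            raise ValueError(f"{gene}: aligned sequences differ in length")
        w = widths.pop()
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t].upper())
            else:
                warnings.warn(f"{gene}: taxon {t} missing; gap-filled")
                rows[t].append("-" * w)
        partitions[gene] = (pos, pos + w)
        pos += w
    return Supermatrix(taxa=taxa, partitions=partitions,
                       matrix={t: "".join(parts) for t, parts in rows.items()})


def _pair_distance(a: str, b: str, model: str) -> float:
    """Distance between two rows, ignoring columns gapped/ambiguous in either."""
    ungapped = trans = transv = 0
    for ca, cb in zip(a, b):
        if ca not in "ACGT" or cb not in "ACGT":
            continue
        ungapped += 1
        if ca == cb:
            continue
        if (ca, cb) in TRANSITIONS:
            trans += 1
        else:
            transv += 1
    if ungapped == 0:
        return math.nan
    p = trans / ungapped
    q = transv / ungapped
    if model == "p_distance":
        return (trans + transv) / ungapped
    if model == "k2p":
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        if w1 <= 0 or w2 <= 0:
            warnings.warn("K2P saturated pair; distance missing")
            return math.nan
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(sm: Supermatrix, model: str = "p_distance") -> DistanceMatrix:
    if len(sm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    n = len(sm.taxa)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dij = _pair_distance(sm.matrix[sm.taxa[i]], sm.matrix[sm.taxa[j]], model)
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=list(sm.taxa), d=d)


def nj_tree(dm: DistanceMatrix, outgroup: set[str] | frozenset[str] = frozenset()
            ) -> TreeNode:
    """Saitou–Nei neighbor joining, rooted on the outgroup branch.

    With an empty or absent outgroup the (arbitrarily rooted) unrooted NJ
    tree is returned with a warning.
    """
    if len(dm.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains missing values")
    sk_dm = _SkbioDM(dm.d, ids=dm.taxa)
    tree = nj(sk_dm)
    out = [t for t in outgroup if t in set(dm.taxa)]
    if not out:
        if outgroup:
            warnings.warn("outgroup absent from matrix; returning unrooted tree")
        return tree
    return root_on_outgroup(tree, out)


def root_on_outgroup(tree: TreeNode, outgroup: list[str]) -> TreeNode:
    """Root an unrooted tree on the branch leading to the outgroup clade."""
    if len(outgroup) == 1:
        node = tree.find(outgroup[0])
    else:
        # ensure the outgroup forms a clade from some rooting, then take lca
        tips = [tree.find(t) for t in outgroup]
        tree = tree.root_at(tips[0].parent)
        node = tree.lca([tree.find(t) for t in outgroup])
        if node.is_root():
            node = tree.find(outgroup[0])
    try:
        rooted = tree.root_at(node, above=True)
    except TypeError:  # older scikit-bio signature
        rooted = tree.root_at(node.parent if node.parent is not None else node)
    return rooted


def to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def same_topology(newick_a: str, newick_b: str) -> bool:
    """Unrooted topological identity (Robinson–Foulds distance zero)."""
    ta = TreeNode.read(_io.StringIO(newick_a))
    tb = TreeNode.read(_io.StringIO(newick_b))
    shared = set(t.name for t in ta.tips()) & set(t.name for t in tb.tips())
    ta = ta.shear(shared)
    tb = tb.shear(shared)
    return ta.compare_rfd(tb) == 0
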