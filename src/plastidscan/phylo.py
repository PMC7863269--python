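"""Distance-based tree building: p-distances, indel distances, neighbor
joining, and bootstrap bipartition support.

Neighbor joining is implemented here with an explicit, deterministic
tie-break (lexicographically smallest pair of leaf-label sets) so repeated
runs and row permutations yield the same topology; negative branch lengths
are clamped to zero with a warning.  Likelihood and Bayesian inference stay
with the dedicated external programs — this module writes alignments in
their input formats and compares topologies instead.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import GAP, NBYTE, Alignment
from .indels import IndelMatrix

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "p_distance",
    "indel_distance",
    "neighbor_joining",
    "bootstrap_support",
]


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=list(self.taxa), columns=list(self.taxa))


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bipartition supports.

    Wraps a newick string; ``as_dendropy`` gives the parsed tree for
    topology comparisons.  Supports are keyed by the smaller side of each
    internal bipartition (frozenset of leaf labels).
    """

    newick: str
    supports: dict[frozenset, float] = field(default_factory=dict)

    def as_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    def leaf_labels(self) -> set[str]:
        t = self.as_dendropy()
        return {l.taxon.label for l in t.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.newick)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick.strip() + "\n")


def tree_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    smaller (ties: lexicographically first) side's leaf-label frozenset."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        if len(below) != len(other):
            side = below if len(below) < len(other) else other
        else:
            side = min(below, other, key=sorted)
        out.add(frozenset(side))
    return out


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise-deletion proportion of differing sites for every pair."""
    mat = alignment.matrix
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    ok = (mat != GAP) & (mat != NBYTE)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            L = int(both.sum())
            if L == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.taxa[i]} and {alignment.taxa[j]}"
                )
            d[i, j] = d[j, i] = float((mat[i][both] != mat[j][both]).sum()) / L
    return DistanceMatrix(taxa=tuple(alignment.taxa), d=d)


def indel_distance(indel_matrix: IndelMatrix) -> DistanceMatrix:
    """Normalized Hamming distance on binary indel characters."""
    m = indel_matrix.matrix
    if m.shape[1] < 1:
        raise ValueError("indel matrix has no characters")
    if (m == m[0]).all():
        raise ValueError("indel matrix is constant: no phylogenetic signal")
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float((m[i] != m[j]).sum()) / m.shape[1]
    return DistanceMatrix(taxa=tuple(indel_matrix.taxa), d=d)


class _Node:
    __slots__ = ("label", "children", "lengths", "leafset")

    def __init__(self, label=None, children=(), lengths=(), leafset=None):
        self.label = label
        self.children = list(children)
        self.lengths = list(lengths)
        self.leafset = leafset or (frozenset([label]) if label else frozenset())

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{c.newick()}:{l:.10f}" for c, l in zip(self.children, self.lengths)
        )
        return f"({inner})"


def neighbor_joining(distances: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken on the lexicographically smallest
    (sorted leaf-label tuple) pair, making the output invariant to the
    input taxon order.
    """
    taxa = list(distances.taxa)
    r = len(taxa)
    if r < 3:
        raise ValueError("need at least 3 taxa")
    d = distances.d.astype(float).copy()
    nodes = [_Node(label=t) for t in taxa]
    clamped = False

    while len(nodes) > 3:
        r = len(nodes)
        R = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - R[i] - R[j]
                key = (
                    round(q, 12),
                    min(tuple(sorted(nodes[i].leafset)), tuple(sorted(nodes[j].leafset))),
                    max(tuple(sorted(nodes[i].leafset)), tuple(sorted(nodes[j].leafset))),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        merged = _Node(
            children=[nodes[i], nodes[j]],
            lengths=[li, lj],
            leafset=nodes[i].leafset | nodes[j].leafset,
        )
        keep = [k for k in range(r) if k not in (i, j)]
        new_d = np.zeros((len(keep) + 1, len(keep) + 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            v = 0.5 * (d[i, ka] + d[j, ka] - d[i, j])
            new_d[a, -1] = new_d[-1, a] = max(v, 0.0)
        nodes = [nodes[k] for k in keep] + [merged]
        d = new_d

    # join the final three around a central node
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lens = [la, lb, lc]
    if min(lens) < 0:
        clamped = True
        lens = [max(x, 0.0) for x in lens]
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    inner = ",".join(f"{n.newick()}:{l:.10f}" for n, l in zip(nodes, lens))
    return PhyloTree(newick=f"({inner});")


def bootstrap_support(
    alignment: Alignment,
    builder=None,
    replicates: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Column bootstrap: support = fraction of replicate trees containing
    each internal bipartition of the full-data tree."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if builder is None:
        builder = lambda aln: neighbor_joining(p_distance(aln))
    rng = np.random.default_rng(seed)
    base = builder(alignment)
    base_bips = base.bipartitions()
    counts = {b: 0 for b in base_bips}
    L = alignment.n_cols
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = Alignment(
            taxa=list(alignment.taxa),
            matrix=alignment.matrix[:, cols],
            ref_taxon=alignment.ref_taxon,
        )
        try:
            rep_bips = builder(rep).bipartitions()
        except ValueError:
            continue
        for b in base_bips:
            if b in rep_bips:
                counts[b] += 1
    base.supports = {b: counts[b] / replicates for b in base_bips}
    return base


def write_relaxed_phylip(alignment: Alignment, path) -> None:
    """Relaxed PHYLIP, the input format of the external ML programs."""
    with open(path, "w") as fh:
        fh.write(f"{alignment.n_taxa} {alignment.n_cols}\n")
        for i, t in enumerate(alignment.taxa):
            fh.write(f"{t}  {alignment.matrix[i].tobytes().decode('ascii')}\n")


def write_nexus(alignment: Alignment, path) -> None:
    """NEXUS data block for external Bayesian inference."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={alignment.n_taxa} NCHAR={alignment.n_cols};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for i, t in enumerate(alignment.taxa):
            fh.write(f"  {t}  {alignment.matrix[i].tobytes().decode('ascii')}\n")
        fh.write("  ;\nEND;\n")
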