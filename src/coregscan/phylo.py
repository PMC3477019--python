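"""Distance-based phylogeny for ortholog promoter vetting.

Implements pairwise distances under p-distance / JC69 / K2P with complete
deletion (every alignment column containing a gap or an ambiguous base in any
sequence is removed globally), Saitou-Nei neighbor joining, UPGMA, and
nonparametric bootstrap support on the point-estimate tree.  All tie-breaks
are by lowest taxon index so runs are deterministic; dendropy provides the
tree container, Newick serialization and bipartition machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .seqio import SequenceRecord

MODELS = ("p-distance", "jc69", "k2p")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise evolutionary distances (substitutions/site)."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("taxa must be unique")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be >= 0")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                fh.write(t + "\t" + "\t".join(f"{x:.6f}" for x in self.d[i]) + "\n")


def complete_deletion(seqs: Sequence[SequenceRecord]) -> list[str]:
    """Drop every column holding '-' or 'N' in any sequence; return the rows."""
    length = len(seqs[0].residues)
    if any(len(s.residues) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    cols = [
        i for i in range(length)
        if all(s.residues[i] not in "-N" for s in seqs)
    ]
    return ["".join(s.residues[i] for i in cols) for s in seqs]


def compute_distance_matrix(
    alignment: Sequence[SequenceRecord],
    model: str = "jc69",
    deletion: str = "complete",
) -> DistanceMatrix:
    """Pairwise distances on the columns surviving complete deletion."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 taxa")
    model = model.lower().replace("_", "-")
    if model == "p":
        model = "p-distance"
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if deletion != "complete":
        raise ValueError("only complete deletion is supported")
    rows = complete_deletion(alignment)
    ncols = len(rows[0])
    if ncols == 0:
        raise ValueError("no alignment columns survive complete deletion")
    taxa = [s.id for s in alignment]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(rows[i], rows[j], model, taxa[i], taxa[j])
    return DistanceMatrix(taxa, d)


def _pair_distance(a: str, b: str, model: str, ta: str, tb: str) -> float:
    L = len(a)
    diffs = transitions = 0
    for x, y in zip(a, b):
        if x != y:
            diffs += 1
            if {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES:
                transitions += 1
    p = diffs / L
    if model == "p-distance":
        return p
    if model == "jc69":
        if p >= 0.75:
            raise ValueError(f"JC69 distance undefined for pair ({ta}, {tb}): p = {p:.3f} >= 0.75")
        return -0.75 * math.log(1 - 4 * p / 3)
    # K2P
    P = transitions / L
    Q = (diffs - transitions) / L
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P distance undefined for pair ({ta}, {tb})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


# ---------------------------------------------------------------------------
# Tree building.  Internal representation: a node is (label, children) where
# children is a list of (child_node, branch_length); leaves have no children.

class _Node:
    __slots__ = ("label", "children", "leafset")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (node, length)
        if self.children:
            self.leafset = frozenset().union(*(c.leafset for c, _ in self.children))
        else:
            self.leafset = frozenset([label])


def _clamp(length: float, what: str) -> float:
    if length < 0:
        if length < -1e-12:
            warnings.warn(f"negative {what} branch length {length:.3g} clamped to 0")
        return 0.0
    return length + 0.0  # normalizes -0.0


def build_nj_tree(dm: DistanceMatrix) -> "PhyloTree":
    """Saitou-Nei neighbor joining; unrooted; lowest-index pair joined on ties."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Node(label=t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        new = _Node(children=[(nodes[i], _clamp(vi, "NJ")), (nodes[j], _clamp(vj, "NJ"))])
        # distances from the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]
    i, j, k = active
    # final trifurcation: three-point formulas
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node(children=[
        (nodes[i], _clamp(vi, "NJ")),
        (nodes[j], _clamp(vj, "NJ")),
        (nodes[k], _clamp(vk, "NJ")),
    ])
    return PhyloTree._from_internal(root, dm.taxa, rooted=False)


def build_upgma_tree(dm: DistanceMatrix) -> "PhyloTree":
    """UPGMA: rooted ultrametric tree with arithmetic-mean cluster distances."""
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes = {i: _Node(label=t) for i, t in enumerate(dm.taxa)}
    heights = {i: 0.0 for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {frozenset((i, j)): dm.d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                dij = d[frozenset((i, j))]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        h = dij / 2
        new = _Node(children=[
            (nodes[i], _clamp(h - heights[i], "UPGMA")),
            (nodes[j], _clamp(h - heights[j], "UPGMA")),
        ])
        k = next_id
        next_id += 1
        for x in active:
            if x in (i, j):
                continue
            dx = (sizes[i] * d[frozenset((i, x))] + sizes[j] * d[frozenset((j, x))]) / (sizes[i] + sizes[j])
            d[frozenset((k, x))] = dx
        nodes[k] = new
        heights[k] = h
        sizes[k] = sizes[i] + sizes[j]
        active = [x for x in active if x not in (i, j)] + [k]
    return PhyloTree._from_internal(nodes[active[0]], dm.taxa, rooted=True)


class PhyloTree:
    """A phylogenetic tree with branch lengths and optional bootstrap supports.

    Thin wrapper over a :class:`dendropy.Tree`; ``supports`` maps the frozenset
    of leaf labels under an internal edge (clade for rooted trees, the
    root-avoiding side of the bipartition for unrooted trees) to a percentage.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool):
        self.tree = tree
        self.rooted = rooted
        self.supports: dict[frozenset, float] = {}

    @classmethod
    def _from_internal(cls, root: _Node, taxa: list[str], rooted: bool) -> "PhyloTree":
        tns = dendropy.TaxonNamespace(taxa)
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = rooted

        def attach(node: _Node, dnode):
            for child, length in node.children:
                dchild = dnode.new_child(edge_length=length)
                if child.children:
                    attach(child, dchild)
                else:
                    dchild.taxon = tns.get_taxon(child.label)
            return dnode

        attach(root, tree.seed_node)
        return cls(tree, rooted)

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def internal_clades(self) -> list[frozenset]:
        """Leaf-sets under internal (non-root, non-leaf) nodes."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
        return out

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal bipartitions: the side not holding the first taxon."""
        all_taxa = frozenset(self.taxa)
        anchor = min(all_taxa)
        out = set()
        for clade in self.internal_clades():
            side = clade if anchor not in clade else all_taxa - clade
            if 1 < len(side) < len(all_taxa) - 1 or (self.rooted and len(side) > 1):
                out.add(side)
        return out

    def path_distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths along the tree (oracle for additivity)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.taxa)
        tx = {t.label: t for t in self.tree.taxon_namespace}
        n = len(taxa)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
        return DistanceMatrix(taxa, d)

    def leaf_depths(self) -> dict[str, float]:
        depths = {}
        for leaf in self.tree.leaf_node_iter():
            total, node = 0.0, leaf
            while node.parent_node is not None:
                total += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = total
        return depths

    def newick(self) -> str:
        """Newick with branch lengths; supports appear as internal node labels."""
        if self.supports:
            all_taxa = frozenset(self.taxa)
            anchor = min(all_taxa)
            for node in self.tree.preorder_node_iter():
                if node is self.tree.seed_node or node.is_leaf():
                    continue
                clade = frozenset(l.taxon.label for l in node.leaf_iter())
                side = clade if (self.rooted or anchor not in clade) else all_taxa - clade
                if side in self.supports:
                    node.label = f"{self.supports[side]:.0f}"
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def bootstrap_support(
    alignment: Sequence[SequenceRecord],
    n_reps: int = 100,
    builder: str = "nj",
    model: str = "jc69",
    seed: int = 0,
    divergence_threshold: Optional[float] = None,
    reference_taxon: Optional[str] = None,
) -> PhyloTree:
    """Point-estimate tree with bootstrap supports (percent of replicates).

    Columns are resampled with replacement per replicate; a replicate whose
    resampled columns all die under complete deletion (or whose distances are
    undefined) is redrawn, with capped retries.  ``divergence_threshold``
    optionally drops taxa whose mean distance to ``reference_taxon`` exceeds
    the threshold before the analysis (off by default).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    build = {"nj": build_nj_tree, "upgma": build_upgma_tree}[builder]
    alignment = list(alignment)
    if divergence_threshold is not None:
        if reference_taxon is None:
            raise ValueError("divergence filtering needs a reference taxon")
        dm0 = compute_distance_matrix(alignment, model=model)
        ref = dm0.taxa.index(reference_taxon)
        keep = {t for k, t in enumerate(dm0.taxa)
                if k == ref or dm0.d[ref, k] <= divergence_threshold}
        alignment = [s for s in alignment if s.id in keep]
    point = build(compute_distance_matrix(alignment, model=model))
    targets = point.bipartitions() if not point.rooted else set(point.internal_clades())
    counts = {b: 0 for b in targets}
    rng = np.random.default_rng(seed)
    L = len(alignment[0].residues)
    for _ in range(n_reps):
        for _attempt in range(100):
            cols = rng.integers(0, L, size=L)
            rep = [
                SequenceRecord(id=s.id, residues="".join(s.residues[c] for c in cols))
                for s in alignment
            ]
            try:
                rep_tree = build(compute_distance_matrix(rep, model=model))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("bootstrap replicate failed after 100 redraws")
        found = rep_tree.bipartitions() if not point.rooted else set(rep_tree.internal_clades())
        for b in targets:
            if b in found:
                counts[b] += 1
    point.supports = {b: 100.0 * c / n_reps for b, c in counts.items()}
    return point
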