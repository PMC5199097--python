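"""Neighbour-joining tree construction with column-bootstrap split support.

Implements the Saitou–Nei agglomeration on a distance matrix: at each step
the pair minimising Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is
joined, with branch lengths from the standard two-point formulas.  Ties in
Q are broken by the lexicographically smallest pair of cluster keys (a
cluster's key is its smallest leaf ID), making runs reproducible.
Negative branch lengths are clamped to zero with the deficit moved to the
partner branch of the join (raw values are logged at debug level).

Trees are carried as (unrooted) dendropy trees wrapped in
:class:`PhyloTree`, which adds canonical bipartition ("split") handling
and Newick round-tripping; bootstrap supports are percentages attached to
internal nodes.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

from .alignment_io import MultipleAlignment
from .distances import DistanceMatrix, distance_matrix

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    """Raised for malformed trees or Newick text."""


class PhyloTree:
    """Unrooted weighted tree over sequence IDs with optional split support."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.split_support: dict[frozenset[str], float] = {}

    # -- basics ---------------------------------------------------------------

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(l.taxon.label for l in self.tree.leaf_node_iter())

    def splits(self) -> frozenset[frozenset[str]]:
        """Canonical non-trivial bipartitions.

        Each internal edge induces a bipartition; the canonical
        representative is the side *not* containing the lexicographically
        smallest leaf, so both orientations hash identically.
        """
        leaves = frozenset(self.leaf_ids)
        anchor = min(leaves)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return frozenset(out)

    def path_length_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        pdm = self.tree.phylogenetic_distance_matrix()
        ids = sorted(self.leaf_ids)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        values = np.zeros((len(ids), len(ids)))
        for i, j in itertools.combinations(range(len(ids)), 2):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            values[i, j] = values[j, i] = d
        return DistanceMatrix(tuple(ids), values, model="path", deletion="pairwise")

    def rename_leaves(self, mapping: dict[str, str]) -> "PhyloTree":
        clone = PhyloTree.from_newick(self.to_newick())
        for taxon in clone.tree.taxon_namespace:
            taxon.label = mapping.get(taxon.label, taxon.label)
        return clone

    # -- Newick ---------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with branch lengths (10 significant digits) and integer
        support percentages as internal node labels."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and not node.is_leaf():
                sup = getattr(node, "support", None)
                if sup is not None:
                    node.label = str(int(round(sup)))
        text = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
        return text

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        if not text or not text.strip():
            raise TreeError("empty Newick string")
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        ptree = cls(tree)
        # recover integer support labels, if present
        leaves = frozenset(ptree.leaf_ids)
        anchor = min(leaves) if leaves else None
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or not node.label:
                continue
            try:
                sup = float(node.label)
            except ValueError:
                continue
            node.support = sup
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                ptree.split_support[side] = sup
        return ptree


def _clamped(l_own: float, l_other: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its partner."""
    if l_own < 0:
        logger.debug("clamping negative NJ branch length %g", l_own)
        l_other += l_own
        l_own = 0.0
    if l_other < 0:
        logger.debug("clamping negative NJ branch length %g", l_other)
        l_own = max(l_own + l_other, 0.0)
        l_other = 0.0
    return l_own, l_other


def nj(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbour joining; requires at least three taxa."""
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    keys: list[str] = []
    for rid in dm.ids:
        taxon = tns.new_taxon(rid)
        nodes.append(dendropy.Node(taxon=taxon))
        keys.append(rid)
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q can be asymmetric in the last ulp, so canonicalise orientations
        candidates = {
            (min(i, j), max(i, j)) for i, j in zip(*np.nonzero(Q == qmin))
        }
        i, j = min(candidates, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d_ij - li
        li, lj = _clamped(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (D[i] + D[j] - d_ij)
        new_key = min(keys[i], keys[j])
        keep = [k for k in range(n) if k not in (i, j)]
        D_next = np.zeros((n - 1, n - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = new_row[keep]
        D = D_next
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d_ab + d_ac - d_bc) / 2.0,
        (d_ab + d_bc - d_ac) / 2.0,
        (d_ac + d_bc - d_ab) / 2.0,
    ]
    for raw in lengths:
        if raw < 0:
            logger.debug("clamping negative terminal NJ branch length %g", raw)
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree)


def bootstrap_support(
    aln: MultipleAlignment,
    model: str = "k2p",
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree with split supports from column-bootstrap replicates.

    Support of a split is the percentage of replicate NJ trees (each built
    from an alignment of columns resampled with replacement) whose split
    set contains it.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base = nj(distance_matrix(aln, model, deletion))
    counts: dict[frozenset[str], int] = {}
    arr = aln.array
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep = MultipleAlignment.from_array(aln.ids, arr[:, cols])
        for split in nj(distance_matrix(rep, model, deletion)).splits():
            counts[split] = counts.get(split, 0) + 1
    leaves = frozenset(base.leaf_ids)
    anchor = min(leaves)
    for node in base.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = leaves - side
        if not (2 <= len(side) <= len(leaves) - 2):
            continue
        pct = 100.0 * counts.get(side, 0) / replicates
        node.support = pct
        base.split_support[side] = pct
    return base
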