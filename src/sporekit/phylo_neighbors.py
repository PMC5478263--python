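"""Support-aware tree analysis: midpoint rooting, phylogenetic-neighbor
(cherry) detection, and synteny classification of neighbor pairs.

Two genes are phylogenetic neighbors when they are separated by a single
internal node whose bootstrap support reaches a threshold (default 95%) —
i.e. they form a well-supported cherry.  Comparing neighbor pairs against a
synteny map separates ordinary orthologous pairs (same syntenic location in
two genomes) from non-syntenic pairs, whose existence points to ectopic
gene conversion or transposition within the family.

Trees are newick with branch lengths in substitutions/site and bootstrap
supports stored as internal-node labels.  Supports are attached to
bipartitions, so they survive re-rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "SupportedTree",
    "parse_supported_newick",
    "midpoint_root",
    "find_neighbor_pairs",
    "SyntenyMap",
    "classify_pairs_by_synteny",
    "read_synteny_map",
]


@dataclass
class SupportedTree:
    """A dendropy tree whose internal-node labels are bootstrap supports
    in [0, 100] (missing where the label is empty)."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for nd in self.tree:
            if nd.edge.length is not None and nd.edge.length < 0:
                raise ValueError(f"negative branch length {nd.edge.length}")
            if not nd.is_leaf() and nd.label not in (None, ""):
                try:
                    float(nd.label)
                except ValueError:
                    raise ValueError(
                        f"internal node label {nd.label!r} is not a number")

    # -- basics ----------------------------------------------------------
    def leaf_labels(self) -> List[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def support_of(self, node: dendropy.Node) -> Optional[float]:
        if node.label in (None, ""):
            return None
        return float(node.label)

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_distance_matrix(self) -> Dict[Tuple[str, str], float]:
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = sorted(self.tree.taxon_namespace, key=lambda t: t.label)
        out = {}
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                out[(a.label, b.label)] = pdm.distance(a, b)
        return out

    # -- bipartition-keyed supports --------------------------------------
    def _canonical_split(self, leafset: FrozenSet[str],
                         all_leaves: FrozenSet[str]) -> FrozenSet[str]:
        ref = min(all_leaves)
        return leafset if ref not in leafset else all_leaves - leafset

    def _split_supports(self) -> Dict[FrozenSet[str], Optional[float]]:
        all_leaves = frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())
        out: Dict[FrozenSet[str], Optional[float]] = {}
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            leafset = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            key = self._canonical_split(leafset, all_leaves)
            if 0 < len(key) < len(all_leaves):
                out[key] = self.support_of(nd)
        return out

    def _restore_supports(self, supports: Dict[FrozenSet[str], Optional[float]]):
        all_leaves = frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            leafset = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            key = self._canonical_split(leafset, all_leaves)
            sup = supports.get(key)
            nd.label = (None if sup is None
                        else format(sup, "g"))


def parse_supported_newick(text: str) -> SupportedTree:
    """Parse a newick string whose internal node labels are support
    values.  Raises ValueError with the parser's position information on
    malformed input."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ValueError(f"malformed newick: {exc}") from exc
    return SupportedTree(tree=tree)


def midpoint_root(stree: SupportedTree, tol: float = 1e-9) -> SupportedTree:
    """Root the tree at the midpoint of the longest leaf-to-leaf path.

    The two endpoints of that path end up equidistant from the root.  Ties
    between equally long paths are broken deterministically by the
    lexicographically smallest (sorted) endpoint pair.  Supports follow
    bipartitions across the re-rooting.  Raises when every branch length
    is zero ("midpoint undefined").
    """
    n_leaves = sum(1 for _ in stree.tree.leaf_node_iter())
    if n_leaves < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    dists = stree.leaf_distance_matrix()
    diameter = max(dists.values())
    if diameter <= 0:
        raise ValueError("midpoint undefined: all branch lengths are zero")
    best_pair = min(p for p, d in dists.items() if d >= diameter - tol)
    supports = stree._split_supports()

    tree = stree.tree.clone(depth=1)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    a, b = leaves[best_pair[0]], leaves[best_pair[1]]
    # node path a -> ... -> common ancestor -> ... -> b
    anc_a = [a] + list(a.ancestor_iter())
    anc_b = [b] + list(b.ancestor_iter())
    in_a = {id(nd): i for i, nd in enumerate(anc_a)}
    k = next(i for i, nd in enumerate(anc_b) if id(nd) in in_a)
    common = anc_b[k]
    path = anc_a[:in_a[id(common)] + 1] + list(reversed(anc_b[:k]))
    # walk from a accumulating branch lengths to find the midpoint edge
    half = diameter / 2.0
    cum = 0.0
    for prev, nxt in zip(path[:-1], path[1:]):
        if nxt is prev.parent_node:        # climbing: edge belongs to prev
            edge, upward = prev.edge, True
        else:                              # descending: edge belongs to nxt
            edge, upward = nxt.edge, False
        elen = edge.length or 0.0
        if cum + elen >= half - tol:
            from_a_end = half - cum        # distance into this edge from prev
            if upward:
                length_head = from_a_end           # head_node side (= prev side)
                length_tail = elen - from_a_end
            else:
                length_tail = from_a_end           # tail side (= prev side)
                length_head = elen - from_a_end
            length_head = max(length_head, 0.0)
            length_tail = max(length_tail, 0.0)
            tree.reroot_at_edge(edge, length1=length_tail, length2=length_head,
                                suppress_unifurcations=True)
            break
        cum += elen
    else:
        raise RuntimeError("midpoint walk failed")  # pragma: no cover
    tree.seed_node.label = None
    rooted = SupportedTree(tree=tree)
    rooted._restore_supports(supports)
    return rooted


def find_neighbor_pairs(
    stree: SupportedTree,
    min_support: float = 95.0,
) -> List[Tuple[str, str]]:
    """All cherries (internal nodes with exactly two leaf children) whose
    support reaches ``min_support``; pairs sorted lexicographically.
    Cherries lacking a support value are excluded with a warning."""
    pairs: List[Tuple[str, str]] = []
    for nd in stree.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        children = nd.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            labels = tuple(sorted(c.taxon.label for c in children))
            sup = stree.support_of(nd)
            if sup is None:
                logger.warning("cherry %s lacks a support value; excluded",
                               labels)
                continue
            if sup >= min_support:
                pairs.append(labels)
    return sorted(pairs)


@dataclass
class SyntenyMap:
    """gene id -> syntenic group id, plus gene id -> genome id.  When
    ``genomes`` is not given, the genome is inferred from the gene name's
    leading alphabetic prefix (e.g. cw9 -> 'cw', wtf9 -> 'wtf')."""

    groups: Dict[str, str]
    genomes: Optional[Dict[str, str]] = None

    def genome_of(self, gene: str) -> str:
        if self.genomes and gene in self.genomes:
            return self.genomes[gene]
        i = 0
        while i < len(gene) and gene[i].isalpha():
            i += 1
        return gene[:i] or gene

    def group_of(self, gene: str) -> str:
        try:
            return self.groups[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} missing from synteny map")


@dataclass
class SyntenyClassification:
    syntenic: List[Tuple[str, str]]
    non_syntenic: List[Tuple[str, str]]

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "syntenic": len(self.syntenic),
            "non_syntenic": len(self.non_syntenic),
            "total": len(self.syntenic) + len(self.non_syntenic),
        }


def classify_pairs_by_synteny(
    pairs: Sequence[Tuple[str, str]],
    synteny: SyntenyMap,
) -> SyntenyClassification:
    """A neighbor pair is syntenic iff both members share a syntenic group
    AND come from different genomes; same-genome pairs (e.g. a tandem
    duplicate pair) are non-syntenic by definition."""
    syn: List[Tuple[str, str]] = []
    non: List[Tuple[str, str]] = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair ({a}, {b}) repeats a leaf")
        same_group = synteny.group_of(a) == synteny.group_of(b)
        diff_genome = synteny.genome_of(a) != synteny.genome_of(b)
        (syn if same_group and diff_genome else non).append((a, b))
    return SyntenyClassification(syntenic=syn, non_syntenic=non)


def read_synteny_map(path) -> SyntenyMap:
    """Two- or three-column TSV: gene, group[, genome]; header optional
    (detected when the first line's second field is 'group')."""
    groups: Dict[str, str] = {}
    genomes: Dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if i == 0 and fields[:2] == ["gene", "group"]:
                continue
            if len(fields) < 2:
                raise ValueError(f"synteny map line {i + 1}: need >=2 columns")
            groups[fields[0]] = fields[1]
            if len(fields) >= 3 and fields[2]:
                genomes[fields[0]] = fields[2]
    return SyntenyMap(groups=groups, genomes=genomes or None)
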