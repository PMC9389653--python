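"""Tree operations for incongruence-based horizontal-transfer inference.

A gene tree of TE copies is compared against the organismal taxonomy by
small parsimony: leaves are labeled with a taxonomic rank (order,
superfamily, ...) and the minimum number of label changes on the tree is
computed by Sankoff dynamic programming with unit costs, generalized to
polytomies (support-collapsing creates them). Any change beyond the
n_labels - 1 needed for mutually monophyletic classes is an "excess event"
— a lower bound on the number of horizontal transfers required to explain
the label distribution. Individual transition edges are materialized as
incongruence records under a canonical (accelerated-transformation style)
resolution of the parsimony labeling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "SupportTree",
    "LabelingResult",
    "TransitionEdge",
    "Incongruence",
    "read_newick",
    "write_newick",
    "collapse_low_support",
    "parsimony_transitions",
    "enumerate_incongruences",
    "neighbor_joining",
    "tree_distance_matrix",
    "same_unrooted_topology",
]


@dataclass
class SupportTree:
    """A phylogeny whose internal nodes may carry branch supports in [0, 1].

    Supports are stored on each dendropy node as ``node.support`` (None when
    absent). ``dialect`` records whether the source encoded supports as
    fractions ("fraction") or percentages ("percent").
    """

    tree: dendropy.Tree
    dialect: str = "fraction"

    def leaf_names(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def clone(self) -> "SupportTree":
        return read_newick(write_newick(self), dialect="fraction")


def read_newick(source, dialect: str = "auto") -> SupportTree:
    """Parse Newick text or a file path into a SupportTree.

    Branch supports are read from internal-node labels. ``dialect`` is
    "fraction" ([0,1]), "percent" ([0,100]) or "auto" (percent iff any
    support value exceeds 1).
    """
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"unparsable Newick: {exc}") from exc

    raw: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.label is None:
            continue
        try:
            raw[node] = float(node.label)
        except ValueError:
            continue  # non-numeric internal label: keep as name, no support
    if dialect == "auto":
        dialect = "percent" if any(v > 1.0 for v in raw.values()) else "fraction"
    scale = 100.0 if dialect == "percent" else 1.0
    for node, v in raw.items():
        s = v / scale
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"support {v} outside range for dialect {dialect!r}")
        node.support = s
        node.label = None
    return SupportTree(tree=tree, dialect=dialect)


def write_newick(stree: SupportTree, path=None) -> str:
    """Serialize a SupportTree; supports are written as internal-node labels
    on the [0, 1] scale. Returns the Newick string; writes to ``path`` too
    when given."""
    t = stree.tree
    for node in t.preorder_node_iter():
        if not node.is_leaf() and getattr(node, "support", None) is not None:
            node.label = format(node.support, "g")
    text = t.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def collapse_low_support(stree: SupportTree, threshold: float = 0.7) -> SupportTree:
    """Contract every internal edge whose support is below ``threshold``
    into a polytomy; the input is left untouched.

    The contracted edge's length is dropped and its children are promoted
    with their own lengths (paths through the contracted edge shorten
    accordingly). Edges without a support value are kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    out = stree.clone()
    t = out.tree
    for node in list(t.postorder_internal_node_iter(exclude_seed_node=True)):
        sup = getattr(node, "support", None)
        if sup is None or sup >= threshold:
            continue
        parent = node.parent_node
        for child in node.child_nodes():
            node.remove_child(child)
            parent.add_child(child)
        parent.remove_child(node)
    return out


# ---------------------------------------------------------------------------
# small parsimony


@dataclass(frozen=True)
class TransitionEdge:
    """An edge on which the canonical parsimony labeling changes state."""

    child_leaf: str                 # lexicographically smallest leaf below
    parent_state: str
    child_state: str
    parent_state_set: frozenset[str]
    child_state_set: frozenset[str]
    ambiguous: bool                 # >1 optimal state above the edge


@dataclass
class LabelingResult:
    """Outcome of minimum label-change counting at one taxonomic rank."""

    label_rank: str
    parsimony_score: int
    n_labels: int
    excess_events: int
    transition_edges: list[TransitionEdge] = field(default_factory=list)


@dataclass(frozen=True)
class Incongruence:
    """A label-uniform clade sitting in a context of another label.

    ``basal_origin`` marks the one transition edge per label interpreted as
    the class's origin (the largest uniform clade of that label); the
    remaining transitions contradict taxonomy and count as incongruences.
    """

    focal_clade: frozenset[str]
    focal_label: str
    context_label: str
    context_leaves: frozenset[str]
    supporting_edge: str
    ambiguous: bool
    basal_origin: bool
    regions_focal: frozenset[str] = frozenset()
    regions_context: frozenset[str] = frozenset()


_INF = 1.0e18


def _min_leaf(node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def _prepare(stree: SupportTree, labels: Mapping[str, str], root_mode: str):
    """Clone, root, and child-sort a tree for parsimony analysis."""
    work = stree.clone()
    t = work.tree
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    for lf in leaves:
        if lf not in labels:
            raise KeyError(f"leaf {lf!r} has no label")

    has_lengths = all(
        e.length is not None for e in t.preorder_edge_iter() if e.head_node.parent_node
    )
    if root_mode == "auto":
        root_mode = "midpoint" if has_lengths else "largest-class"
    if root_mode == "midpoint":
        if not has_lengths:
            raise ValueError("midpoint rooting needs branch lengths")
        t.reroot_at_midpoint(update_bipartitions=False)
    elif root_mode == "largest-class":
        counts: dict[str, int] = {}
        for lf in leaves:
            counts[labels[lf]] = counts.get(labels[lf], 0) + 1
        big = max(sorted(counts), key=lambda lab: counts[lab])
        class_leaves = [lf for lf in leaves if labels[lf] == big]
        t.is_rooted = True
        mrca = t.mrca(taxon_labels=class_leaves)
        if mrca is not t.seed_node:
            t.reroot_at_node(mrca, update_bipartitions=False)
    elif root_mode != "keep":
        raise ValueError(f"unknown root_mode {root_mode!r}")

    # deterministic ordering: children sorted by their smallest descendant leaf
    for node in t.postorder_node_iter():
        node._min_leaf = (
            node.taxon.label if node.is_leaf()
            else min(c._min_leaf for c in node.child_nodes())
        )
    for node in t.preorder_internal_node_iter():
        node.set_child_nodes(sorted(node.child_nodes(), key=lambda c: c._min_leaf))
    return work


def _sankoff(tree: dendropy.Tree, labels: Mapping[str, str]):
    """Up-down Sankoff with unit costs over arbitrary out-degree.

    Returns (label_list, score, assigned, optimal_sets) where ``assigned``
    maps node -> state index under the canonical resolution and
    ``optimal_sets`` maps node -> boolean vector of states attainable in
    some minimum-cost labeling.
    """
    label_list = sorted(set(labels[lf.taxon.label] for lf in tree.leaf_node_iter()))
    k = len(label_list)
    idx = {lab: i for i, lab in enumerate(label_list)}

    down: dict = {}
    contrib: dict = {}  # child -> its min-cost contribution vector to parent
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.full(k, _INF)
            vec[idx[labels[node.taxon.label]]] = 0.0
        else:
            vec = np.zeros(k)
            for c in node.child_nodes():
                cvec = np.minimum(down[c], down[c].min() + 1.0)
                contrib[c] = cvec
                vec = vec + cvec
        down[node] = vec

    root = tree.seed_node
    score = int(round(down[root].min()))

    up: dict = {root: np.zeros(k)}
    for node in tree.preorder_internal_node_iter():
        for c in node.child_nodes():
            other = down[node] - contrib[c] + up[node]
            up[c] = np.minimum(other, other.min() + 1.0)
    optimal_sets = {
        n: (down[n] + up[n]) <= score + 0.5 for n in tree.preorder_node_iter()
    }

    # canonical assignment; ties resolved toward early (rootward) changes,
    # then lexicographically by label
    assigned: dict = {}
    root_cand = np.flatnonzero(down[root] <= down[root].min() + 0.5)
    assigned[root] = int(root_cand[0])
    for node in tree.preorder_internal_node_iter():
        s_v = assigned[node]
        for c in node.child_nodes():
            arr = down[c] + 1.0
            arr[s_v] -= 1.0
            cand = np.flatnonzero(arr <= arr.min() + 0.5)
            non_parent = [int(x) for x in cand if x != s_v]
            if len(cand) > 1 and non_parent:
                assigned[c] = non_parent[0]
            else:
                assigned[c] = int(cand[0])
    return label_list, score, assigned, optimal_sets


def parsimony_transitions(
    stree: SupportTree,
    labels: Mapping[str, str],
    label_rank: str = "label",
    root_mode: str = "auto",
) -> LabelingResult:
    """Minimum number of label changes explaining the leaf labeling, with
    the canonical transition edges.

    ``excess_events`` subtracts the n_labels - 1 changes that mutually
    monophyletic classes would already require; it lower-bounds the number
    of horizontal transfers needed to explain the distribution.
    """
    work = _prepare(stree, labels, root_mode)
    t = work.tree
    label_list, score, assigned, osets = _sankoff(t, labels)
    edges = []
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None or assigned[node] == assigned[parent]:
            continue
        edges.append(
            TransitionEdge(
                child_leaf=node._min_leaf,
                parent_state=label_list[assigned[parent]],
                child_state=label_list[assigned[node]],
                parent_state_set=frozenset(
                    label_list[i] for i in np.flatnonzero(osets[parent])
                ),
                child_state_set=frozenset(
                    label_list[i] for i in np.flatnonzero(osets[node])
                ),
                ambiguous=int(osets[parent].sum()) > 1,
            )
        )
    n_labels = len(label_list)
    return LabelingResult(
        label_rank=label_rank,
        parsimony_score=score,
        n_labels=n_labels,
        excess_events=score - (n_labels - 1),
        transition_edges=edges,
    )


def _region_leaves(start, state, assigned) -> frozenset[str]:
    """Leaves in the maximal connected same-state region containing start."""
    seen, stack, leaves = {start}, [start], []
    while stack:
        node = stack.pop()
        if node.is_leaf():
            leaves.append(node.taxon.label)
        nbrs = list(node.child_nodes())
        if node.parent_node is not None:
            nbrs.append(node.parent_node)
        for nb in nbrs:
            if nb not in seen and assigned[nb] == state:
                seen.add(nb)
                stack.append(nb)
    return frozenset(leaves)


def enumerate_incongruences(
    stree: SupportTree,
    labels: Mapping[str, str],
    root_mode: str = "auto",
) -> list[Incongruence]:
    """Materialize each canonical transition edge as an Incongruence.

    The focal clade is the maximal label-uniform region below the edge; the
    context leaves are the uniform region above it. Per label, the largest
    focal clade is flagged ``basal_origin`` (the class's single origin on
    the tree); every other transition of that label — and every transition
    into the root's background state — is a genuine incongruence. Edges
    whose above-edge parsimony state is not unique are flagged ambiguous;
    headline counts should use unambiguous, non-basal records.
    """
    work = _prepare(stree, labels, root_mode)
    t = work.tree
    label_list, score, assigned, osets = _sankoff(t, labels)
    root_state = assigned[t.seed_node]

    records = []
    for node in t.preorder_node_iter():
        parent = node.parent_node
        if parent is None or assigned[node] == assigned[parent]:
            continue
        focal = _region_leaves(node, assigned[node], assigned)
        context = _region_leaves(parent, assigned[parent], assigned)
        records.append(
            Incongruence(
                focal_clade=focal,
                focal_label=label_list[assigned[node]],
                context_label=label_list[assigned[parent]],
                context_leaves=context,
                supporting_edge=node._min_leaf,
                ambiguous=int(osets[parent].sum()) > 1,
                basal_origin=False,
            )
        )

    # per-label basal designation: largest focal clade, unless the label is
    # the root's background state (its origin is the root itself)
    by_label: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_label.setdefault(rec.focal_label, []).append(i)
    out = list(records)
    for lab, idxs in by_label.items():
        if lab == label_list[root_state]:
            continue
        basal_i = max(idxs, key=lambda i: (len(out[i].focal_clade),
                                           tuple(sorted(out[i].focal_clade))))
        rec = out[basal_i]
        out[basal_i] = Incongruence(
            focal_clade=rec.focal_clade, focal_label=rec.focal_label,
            context_label=rec.context_label, context_leaves=rec.context_leaves,
            supporting_edge=rec.supporting_edge, ambiguous=rec.ambiguous,
            basal_origin=True,
        )
    return sorted(out, key=lambda r: tuple(sorted(r.focal_clade)))


# ---------------------------------------------------------------------------
# neighbor joining (closed-loop synthetic use; ML inference is consumed,
# not produced, in real analyses)


def neighbor_joining(dist: np.ndarray, ids: Sequence[str]) -> SupportTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    On an additive matrix the tree's path lengths reproduce the input
    exactly. The returned tree is unrooted (basal trifurcation) and carries
    no supports.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if n != len(ids):
        raise ValueError("ids length must match matrix size")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix diagonal must be zero")

    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(dist, ids=list(ids)))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return read_newick(buf.getvalue())


def tree_distance_matrix(stree: SupportTree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``ids``."""
    pdm = stree.tree.phylogenetic_distance_matrix()
    taxa = {tx.label: tx for tx in stree.tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out


def same_unrooted_topology(a: SupportTree, b: SupportTree) -> bool:
    """True iff the two trees induce identical unrooted split sets."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=write_newick(a), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=write_newick(b), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    from dendropy.calculate import treecompare

    return treecompare.symmetric_difference(ta, tb, is_bipartitions_updated=True) == 0
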