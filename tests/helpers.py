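"""Shared test utilities: random tree generation and independent oracles.

The oracles here deliberately avoid the library's own algorithms: parsimony
is checked by exhaustive enumeration over all internal-node labelings, and
interval coverage by a per-base bitmap.
"""

from __future__ import annotations

import numpy as np

from httdetect.treeops import SupportTree, read_newick


def random_tree_newick(
    rng: np.random.Generator,
    n_leaves: int,
    polytomy_prob: float = 0.3,
    with_lengths: bool = True,
    with_supports: bool = False,
) -> str:
    """Random rooted tree over leaves L0..L{n-1}, built by repeated joins of
    2 (or 3, with ``polytomy_prob``) subtrees."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 3 if (len(nodes) > 2 and rng.random() < polytomy_prob) else 2
        picks = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        parts = [nodes.pop(i) for i in picks]
        if with_lengths:
            parts = [f"{p}:{rng.uniform(0.5, 2.0):.4f}" for p in parts]
        sup = f"{rng.uniform(0.0, 1.0):.2f}" if with_supports else ""
        nodes.append("(" + ",".join(parts) + ")" + sup)
    return nodes[0] + ";"


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> SupportTree:
    return read_newick(random_tree_newick(rng, n_leaves, polytomy_prob=0.0))


def random_labels(rng: np.random.Generator, n_leaves: int, n_labels: int):
    labs = [f"lab{i}" for i in range(n_labels)]
    # force every label to occur at least once
    choice = list(rng.integers(0, n_labels, n_leaves))
    for i in range(min(n_labels, n_leaves)):
        choice[i] = i
    return {f"L{i}": labs[choice[i]] for i in range(n_leaves)}


def brute_force_parsimony(stree: SupportTree, labels: dict[str, str]) -> int:
    """Minimum label changes by exhaustive enumeration of internal states."""
    tree = stree.tree
    label_list = sorted(set(labels.values()))
    k = len(label_list)
    idx = {lab: i for i, lab in enumerate(label_list)}
    internal = list(tree.preorder_internal_node_iter())
    m = len(internal)
    col = {id(n): j for j, n in enumerate(internal)}
    combos = np.arange(k**m, dtype=np.int64)
    assign = np.empty((k**m, m), dtype=np.int8)
    for j in range(m):
        assign[:, j] = (combos // (k**j)) % k
    cost = np.zeros(k**m, dtype=np.int32)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        pcol = assign[:, col[id(parent)]]
        if node.is_leaf():
            cost += pcol != idx[labels[node.taxon.label]]
        else:
            cost += pcol != assign[:, col[id(node)]]
    return int(cost.min())


def bitmap_coverage(intervals, query_length: int) -> int:
    """Per-base membership count for 1-based inclusive intervals."""
    mask = np.zeros(query_length, dtype=bool)
    for s, e in intervals:
        mask[s - 1 : e] = True
    return int(mask.sum())
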