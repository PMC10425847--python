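"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (double loops, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import squareform


def naive_average_linkage(condensed: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) unweighted average linkage.

    Returns merges as (left member set, right member set, height); cluster
    identity is carried by member sets so the comparison with any
    implementation is representation-independent.
    """
    D = squareform(condensed)
    n = D.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            key = (d, sorted(clusters[a])[0], sorted(clusters[b])[0])
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((clusters[a], clusters[b], float(d)))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def merge_partitions(merges) -> list[tuple[frozenset, float]]:
    """Height-tagged merged sets, the tie-robust comparison view."""
    return sorted(
        ((left | right, round(h, 10)) for left, right, h in merges),
        key=lambda t: (t[1], sorted(t[0])),
    )


def dendrogram_partitions(dendrogram) -> list[tuple[frozenset, float]]:
    """Same view computed from a package Dendrogram."""
    out = []
    for k, (_, _, h) in enumerate(dendrogram.merges):
        node = dendrogram.n_leaves + k
        out.append((frozenset(dendrogram.leaves_under(node)), round(h, 10)))
    return sorted(out, key=lambda t: (t[1], sorted(t[0])))


def exhaustive_dollo_min(tree, trait: dict[str, bool]) -> int:
    """Minimal number of loss edges explaining the leaf states, by
    exhaustive search over subsets of all-absent edges."""
    leafsets = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        leafsets.append(leaves)
    absent = frozenset(s for s, present in trait.items() if not present)
    usable = [ls for ls in leafsets if ls and ls <= absent]
    if not absent:
        return 0
    for size in range(1, len(usable) + 1):
        for combo in itertools.combinations(usable, size):
            if frozenset().union(*combo) == absent:
                return size
    raise AssertionError("absent set not coverable")  # cannot happen


def all_leaf_orderings(merges: list[tuple[int, int, float]], n_leaves: int):
    """Every leaf order obtainable by flipping children at internal nodes."""
    def orders(node: int):
        if node < n_leaves:
            yield [node]
            return
        left, right, _ = merges[node - n_leaves]
        for lo in orders(left):
            for ro in orders(right):
                yield lo + ro
                yield ro + lo

    root = n_leaves + len(merges) - 1
    yield from orders(root)


def random_binary_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary tree over the labels, as Newick."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [
            f"({nodes[i]},{nodes[j]})"
        ]
    return nodes[0] + ";"
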