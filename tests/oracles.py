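"""Independent oracles used by the test suite.

These deliberately take the slow, direct route — exhaustive enumeration of
ancestral states for the tree likelihood, and full expansion of repeat
combinations into concrete regular expressions for motif matching — so they
share no code path with the implementations they check.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"


def enumeration_log_likelihood(phylo_tree, column, model, rate):
    """Column log-likelihood by summing over all internal-state assignments."""
    t = phylo_tree.tree
    nodes = list(t.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    obs = dict(zip(phylo_tree.leaf_labels, column))
    transition = {}
    for n in nodes:
        if n is not t.seed_node:
            transition[n] = model.transition_matrix((n.edge.length or 0.0) * rate)
    total = 0.0
    for assign in itertools.product(range(20), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = model.pi[amap[t.seed_node]]
        for n in nodes:
            if n is t.seed_node:
                continue
            parent_state = amap[n.parent_node]
            if n.is_leaf():
                ch = obs[n.taxon.label]
                p *= 1.0 if ch in ("-", "X") else transition[n][parent_state, AA.index(ch)]
            else:
                p *= transition[n][parent_state, amap[n]]
        total += p
    return math.log(total)


def brute_force_scan(pattern, sequence):
    """All (start, end) hit spans by regex fullmatch of every repeat expansion.

    Expands the pattern's tokens into every combination of concrete repeat
    counts, renders each as a plain character-class regex, and tests every
    substring.  Coordinates are 1-based inclusive.
    """
    expansions = []
    choices = [range(t.min_repeat, t.max_repeat + 1) for t in pattern.tokens]
    for combo in itertools.product(*choices):
        parts = []
        for tok, count in zip(pattern.tokens, combo):
            cls = "[" + "".join(sorted(tok.residues)) + "]"
            parts.append(cls * count)
        expansions.append(re.compile("".join(parts)))
    spans = set()
    n = len(sequence)
    for start in range(n):
        for end in range(start + 1, n + 1):
            sub = sequence[start:end]
            if any(rx.fullmatch(sub) for rx in expansions):
                spans.add((start + 1, end))
    return spans


def column_diversity(alignment, col0):
    """Mean pairwise mismatch fraction of a column (gap/X pairs skipped)."""
    col = [ch for ch in alignment.column(col0) if ch not in ("-", "X")]
    n = len(col)
    if n < 2:
        return 0.0
    mism = sum(
        1 for i in range(n) for j in range(i + 1, n) if col[i] != col[j]
    )
    return mism / (n * (n - 1) / 2)


def random_additive_matrix(rng, n_taxa):
    """A distance matrix realised by a random binary tree with positive edges.

    Returns (D, ids, newick) where D is exactly the tree's path-length metric.
    """
    ids = [f"x{i}" for i in range(n_taxa)]
    # random binary topology by sequential attachment
    import dendropy

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    left = dendropy.Node(taxon=taxa.get_taxon(ids[0]))
    right = dendropy.Node(taxon=taxa.get_taxon(ids[1]))
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    leaves = [left, right]
    for sid in ids[2:]:
        target = leaves[rng.integers(len(leaves))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        new_leaf = dendropy.Node(taxon=taxa.get_taxon(sid))
        mid.add_child(new_leaf)
        leaves.append(new_leaf)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.5, 3.0))
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
                D[i, j] = D[j, i] = d
    return D, ids
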