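"""Independent oracles used by the test suite.

These deliberately avoid the package's own likelihood and bipartition code:
the likelihood oracle sums exhaustively over all internal-state assignments,
and the tree-distance oracles go through dendropy's bipartition encoding.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from phyloerr.errormodel import ErrorSpec, tip_vector
from phyloerr.phylotree import PhyloTree, TreeNode, write_newick
from phyloerr.seqio import Alignment
from phyloerr.substmodel import SubstModel, transition_matrix


def brute_force_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: SubstModel, spec: ErrorSpec
) -> float:
    """Exhaustive sum over all internal-node state assignments."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_tip]
    tips = [n for n in nodes if n.is_tip]
    pmats = {id(n): transition_matrix(model, n.length) for n in nodes if n.parent is not None}
    col = {name: i for i, name in enumerate(aln.taxon_names)}
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, states)}
            pr = 0.25  # uniform root frequency
            for n in internals:
                if n.parent is not None:
                    pr *= pmats[id(n)][state[id(n.parent)], state[id(n)]]
            for tp in tips:
                sym = aln.sequences[col[tp.name]][site]
                v = tip_vector(sym, spec.rate_for(tp.name))
                pr *= pmats[id(tp)][state[id(tp.parent)]] @ v
            site_lik += pr
        total += np.log(site_lik)
    return float(total)


def _dendropy_pair(nwk1: str, nwk2: str):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    return t1, t2


def dendropy_rf(tree1: PhyloTree, tree2: PhyloTree) -> int:
    t1, t2 = _dendropy_pair(write_newick(tree1), write_newick(tree2))
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


def dendropy_rfl(tree1: PhyloTree, tree2: PhyloTree) -> float:
    """Sum of absolute branch-length differences over the union of splits
    (pendant edges included), computed from dendropy's bipartition encoding."""
    t1, t2 = _dendropy_pair(write_newick(tree1), write_newick(tree2))
    maps = []
    for t in (t1, t2):
        t.encode_bipartitions()
        lengths: dict[int, float] = {}
        for edge in t.preorder_edge_iter():
            if edge.head_node is t.seed_node:
                continue
            key = edge.bipartition.split_bitmask
            lengths[key] = lengths.get(key, 0.0) + (edge.length or 0.0)
        maps.append(lengths)
    m1, m2 = maps
    return sum(abs(m1.get(k, 0.0) - m2.get(k, 0.0)) for k in set(m1) | set(m2))


def random_binary_tree(names: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random fully-resolved unrooted tree (trifurcating root) with random
    branch lengths in [0.05, 1.05)."""
    if len(names) < 3:
        raise ValueError("need at least 3 names")
    root = TreeNode()
    for name in names[:3]:
        root.add_child(TreeNode(name, float(rng.uniform(0.05, 1.05))))
    tree = PhyloTree(root, rooted=False)
    for name in names[3:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        joint = TreeNode(None, float(rng.uniform(0.05, 1.05)))
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        joint.add_child(target)
        joint.add_child(TreeNode(name, float(rng.uniform(0.05, 1.05))))
        tree = PhyloTree(tree.root, rooted=False)
    return tree
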