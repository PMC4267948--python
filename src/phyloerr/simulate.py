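"""Simulators: clocklike branching-process trees, K2P sequence evolution,
miscall-error injection, and a Bernoulli-site polymorphism fixture.

All generators take a ``seed`` (anything accepted by
``numpy.random.default_rng``) and are bit-reproducible for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errormodel import ErrorSpec
from .phylotree import PhyloTree, TreeNode
from .seqio import Alignment
from .substmodel import BASES, SubstModel, transition_matrix

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimulationConfig:
    """One simulation condition.

    ``t`` is the tree-size scaling parameter of the branching process: each
    of the k extant lineages splits at rate ``1/t``, so the interval spent
    with k lineages is exponential with mean ``t/k`` (t/2 for the rootmost
    interval) and larger ``t`` gives longer, more informative trees.
    """

    n_taxa: int = 20
    t: float = 1e-3
    seq_length: int = 20_000
    true_error: ErrorSpec = field(default_factory=ErrorSpec)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if not self.t > 0:
            raise ValueError("t must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_yule_tree(n_taxa: int, t: float, seed) -> PhyloTree:
    """Clocklike pure-birth tree with per-lineage split rate ``1/t``.

    Starts from two lineages at the root; while fewer than ``n_taxa``
    lineages exist, waits an Exp(k/t) interval and splits a uniformly chosen
    lineage; after reaching ``n_taxa`` lineages a final Exp(n_taxa/t)
    interval is appended so terminal branches are non-degenerate.  The
    returned tree is ultrametric with tips at height 0 and carries node
    heights.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not (t > 0 and np.isfinite(t)):
        raise ValueError("t must be positive and finite")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    birth = {id(root): 0.0}
    active = [root.add_child(TreeNode()), root.add_child(TreeNode())]
    birth[id(active[0])] = birth[id(active[1])] = 0.0
    now = 0.0
    while len(active) < n_taxa:
        k = len(active)
        now += rng.exponential(t / k)
        node = active.pop(int(rng.integers(k)))
        node.length = now - birth[id(node)]
        for _ in range(2):
            child = node.add_child(TreeNode())
            birth[id(child)] = now
            active.append(child)
    now += rng.exponential(t / n_taxa)
    for i, tip in enumerate(active):
        tip.name = f"t{i + 1}"
        tip.length = now - birth[id(tip)]
    tree = PhyloTree(root, rooted=True)
    # heights: every tip sits at 0, internal height = tip distance below it
    for node in tree.postorder():
        if node.is_tip:
            node.height = 0.0
        else:
            node.height = node.children[0].height + node.children[0].length
    return tree


def evolve_alignment(tree: PhyloTree, model: SubstModel, seq_length: int, seed) -> Alignment:
    """Simulate sequences on the tree under the K2P model.

    The root sequence is uniform over {A, C, G, T} per site; each branch
    mutates sites independently according to the branch's transition matrix.
    Only resolved bases are produced.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            seqs[id(node)] = rng.integers(0, 4, size=seq_length, dtype=np.int8)
            continue
        parent_seq = seqs[id(node.parent)]
        cum = transition_matrix(model, node.length).cumsum(axis=1)
        u = rng.random(seq_length)
        child_seq = np.empty(seq_length, dtype=np.int8)
        for x in range(4):
            mask = parent_seq == x
            child_seq[mask] = np.searchsorted(cum[x], u[mask], side="right")
        np.clip(child_seq, 0, 3, out=child_seq)
        seqs[id(node)] = child_seq
    tips = tree.tips()
    return Alignment(
        [tip.name for tip in tips],
        ["".join(BASES[c] for c in seqs[id(tip)]) for tip in tips],
    )


def inject_errors(aln: Alignment, spec: ErrorSpec, seed) -> Alignment:
    """Independently miscall each base with its taxon's epsilon.

    A miscalled base is replaced by one of the three other bases uniformly.
    Error injection models the sequencing step, so it applies to resolved
    bases only; ambiguity codes in the input raise ``ValueError``.
    """
    spec.validate_taxa(aln.taxon_names)
    resolved = set(BASES)
    out = []
    rng = np.random.default_rng(seed)
    for name, seq in zip(aln.taxon_names, aln.sequences):
        extra = set(seq) - resolved
        if extra:
            raise ValueError(
                f"taxon {name!r} contains non-resolved symbols {sorted(extra)}; "
                "error injection requires plain A/C/G/T data"
            )
        eps = spec.rate_for(name)
        codes = np.fromiter((_BASE_TO_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
        mask = rng.random(len(seq)) < eps
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.int8)
        codes[mask] = (codes[mask] + shift) % 4
        out.append("".join(BASES[c] for c in codes))
    return Alignment(list(aln.taxon_names), out)


def bernoulli_snp_alignment(n_taxa: int, seq_length: int, m: float, seed) -> Alignment:
    """Simple polymorphism fixture: each site is independently polymorphic
    with probability ``m``, in which case one uniformly chosen taxon carries
    a different uniformly chosen base; otherwise all taxa share one uniform
    base."""
    if not (0.0 <= m <= 1.0):
        raise ValueError("m must lie in [0, 1]")
    if n_taxa < 2 or seq_length < 1:
        raise ValueError("need n_taxa >= 2 and seq_length >= 1")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=seq_length, dtype=np.int8)
    poly = rng.random(seq_length) < m
    carrier = rng.integers(0, n_taxa, size=seq_length)
    shift = rng.integers(1, 4, size=seq_length, dtype=np.int8)
    matrix = np.tile(base, (n_taxa, 1))
    sites = np.nonzero(poly)[0]
    matrix[carrier[sites], sites] = (base[sites] + shift[sites]) % 4
    return Alignment(
        [f"t{i + 1}" for i in range(n_taxa)],
        ["".join(BASES[c] for c in row) for row in matrix],
    )
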