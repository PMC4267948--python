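"""Maximum-likelihood tree inference with and without a molecular clock.

The search follows the classic scheme: seeded random-order stepwise addition
(every branch of the growing tree is tried for each new taxon and the best
log-likelihood placement kept) followed by nearest-neighbor-interchange
sweeps until no rearrangement improves the log-likelihood beyond the
convergence threshold.  Branch lengths (or, in clock mode, node heights) are
optimized by bounded one-dimensional search per parameter, swept to
convergence; the declared sequencing-error rate is a fixed input of the
likelihood, never estimated.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errormodel import ErrorSpec, tip_vector
from .likelihood import LikelihoodWorkspace, PI
from .phylotree import PhyloTree, TreeNode
from .seqio import Alignment, compress_patterns
from .substmodel import BASES, SubstModel, TRANSITION_PARTNER, build_model, _matrix_from_probs

logger = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    """Knobs of the ML search.

    ``declared_error`` is the error rate assumed during inference (which may
    differ from the rate the data were generated with); ``clock`` selects
    ultrametric (Dnamlk-style) versus unconstrained (Dnaml-style) branch
    lengths.
    """

    clock: bool = False
    declared_error: ErrorSpec = field(default_factory=ErrorSpec)
    ts_tv_ratio: float = 2.0
    seed: int = 0
    bl_min: float = 1e-8
    bl_max: float = 100.0
    tol_lnl: float = 1e-6
    max_passes: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.bl_min < self.bl_max):
            raise ValueError("need 0 < bl_min < bl_max")
        if not self.tol_lnl > 0:
            raise ValueError("tol_lnl must be positive")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


# ---------------------------------------------------------------------------
# pairwise distances


def _pair_counts(seq1: str, seq2: str) -> tuple[int, int, int]:
    """(identical, transition, transversion) site counts for resolved pairs."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    resolved = set(BASES)
    for seq in (seq1, seq2):
        extra = set(seq) - resolved
        if extra:
            raise ValueError(f"pairwise distance needs resolved bases, found {sorted(extra)}")
    same = ts = tv = 0
    idx = {b: i for i, b in enumerate(BASES)}
    for a, b in zip(seq1, seq2):
        if a == b:
            same += 1
        elif idx[b] == TRANSITION_PARTNER[idx[a]]:
            ts += 1
        else:
            tv += 1
    return same, ts, tv


def k2p_distance(p_transition: float, q_transversion: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    arg1 = 1.0 - 2.0 * p_transition - q_transversion
    arg2 = 1.0 - 2.0 * q_transversion
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise ValueError("saturated proportions: K2P distance undefined")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def ml_pairwise_distance(
    seq1: str,
    seq2: str,
    model: SubstModel,
    epsilon: float,
    *,
    bl_max: float = 100.0,
) -> float:
    """Two-taxon ML branch length under K2P with error-adjusted tips.

    The likelihood is maximized over the transition and transversion
    components of the path jointly (the transition/transversion ratio is
    profiled out), so with ``epsilon = 0`` the estimate equals the
    closed-form K2P distance.  ``model`` seeds the numeric search.  Saturated
    data fall back to ``bl_max`` with a warning.
    """
    same, ts, tv = _pair_counts(seq1, seq2)
    n = same + ts + tv
    p_hat, q_hat = ts / n, tv / n
    if epsilon == 0.0:
        # exact analytic maximizer of the profiled two-parameter likelihood
        try:
            return min(k2p_distance(p_hat, q_hat), bl_max)
        except ValueError:
            warnings.warn("saturated data: returning bl_max", stacklevel=2)
            return bl_max

    # representative base pairs for the three pair classes
    v_same = _pair_class_vectors("A", "A", epsilon)
    v_ts = _pair_class_vectors("A", "G", epsilon)
    v_tv = _pair_class_vectors("A", "C", epsilon)
    counts = np.array([same, ts, tv], dtype=float)

    def nll(params: np.ndarray) -> float:
        s, u = params
        if s < 0 or u < 0:
            return 1e12 + 1e12 * (max(0.0, -s) + max(0.0, -u))
        e1 = math.exp(-4.0 * u)
        e2 = math.exp(-2.0 * (s + u))
        p = _matrix_from_probs(0.25 + 0.25 * e1 - 0.5 * e2, 0.25 - 0.25 * e1)
        lik = [
            float(np.einsum("i,ij,j->", PI * v1, p, v2))
            for v1, v2 in (v_same, v_ts, v_tv)
        ]
        return -float(np.dot(counts, np.log(np.maximum(lik, 1e-300))))

    try:
        d0 = k2p_distance(p_hat, q_hat)
    except ValueError:
        d0 = 1.0
    beta0 = 1.0 / (2.0 * (model.ts_tv_ratio + 1.0))
    x0 = np.array([max(d0 * (1 - 2 * beta0), 1e-6), max(d0 * beta0, 1e-6)])
    res = minimize(
        nll,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000, "maxfev": 4000},
    )
    s, u = np.maximum(res.x, 0.0)
    d = s + 2.0 * u
    if d >= bl_max:
        warnings.warn("saturated data: returning bl_max", stacklevel=2)
        return bl_max
    return float(d)


def _pair_class_vectors(b1: str, b2: str, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    return tip_vector(b1, epsilon), tip_vector(b2, epsilon)


# ---------------------------------------------------------------------------
# branch-length optimization (non-clock)


def _maximize_1d(objective, lo: float, hi: float, x0: float, xatol: float):
    """Bounded 1-D maximization robust to the flat saturation plateau.

    The likelihood of a branch length (or node height) flattens once the
    branch saturates, so a single bounded search over a wide interval can
    stall on the plateau.  Search instead in a window around the current
    value, widening it only while the optimum presses against the window's
    upper edge.  Returns ``(argmax, max_value)``.
    """
    window = min(hi, lo + max(10.0 * (x0 - lo), 0.1))
    while True:
        res = minimize_scalar(
            lambda x: -objective(x),
            bounds=(lo, window),
            method="bounded",
            options={"xatol": xatol, "maxiter": 200},
        )
        if window >= hi or res.x < 0.9 * window:
            return float(res.x), float(-res.fun)
        window = min(hi, lo + (window - lo) * 10.0)


def _optimize_edges(
    ws: LikelihoodWorkspace,
    nodes: list[TreeNode],
    config: InferenceConfig,
    passes: int,
    xatol: float = 1e-10,
) -> float:
    """Sweep bounded 1-D optimization over the given branches, in place.

    Returns the final log-likelihood; never decreases it.
    """
    lnl = ws.log_likelihood()
    for p in range(passes):
        prev = lnl
        for node in nodes:
            obj = ws.edge_objective(node)
            current = obj(node.length)
            best_x, best_val = _maximize_1d(obj, config.bl_min, config.bl_max, node.length, xatol)
            if best_val > current:
                node.length = best_x
                ws.refresh()
        ws.refresh()
        lnl = ws.log_likelihood()
        logger.debug("branch sweep %d: lnL = %.6f", p + 1, lnl)
        if lnl - prev < config.tol_lnl:
            break
    return lnl


def optimize_branch_lengths(tree, patterns, model, spec, config):
    """ML branch lengths on a fixed topology (non-clock).

    Returns ``(tree_copy_with_updated_lengths, lnL)``.
    """
    tree = tree.copy()
    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    edges = [n for n in tree.postorder() if n.parent is not None]
    lnl = _optimize_edges(ws, edges, config, passes=config.max_passes)
    if not np.isfinite(lnl):
        raise ArithmeticError("non-finite likelihood during branch optimization")
    return tree, lnl


# ---------------------------------------------------------------------------
# clock (ultrametric) optimization


def _init_heights(tree: PhyloTree) -> None:
    """Force tips to height 0 and each internal node above its children."""
    for node in tree.postorder():
        if node.is_tip:
            node.height = 0.0
        else:
            node.height = max(c.height + max(c.length, 1e-9) for c in node.children)
    tree.set_lengths_from_heights()


def _clock_sweep(
    ws: LikelihoodWorkspace,
    tree: PhyloTree,
    config: InferenceConfig,
    passes: int,
) -> float:
    """Optimize internal node heights by bounded 1-D search, in place."""

    def lnl_with_height(node: TreeNode, h: float) -> float:
        node.height = h
        if node.parent is not None:
            node.length = node.parent.height - h
        for child in node.children:
            child.length = h - child.height
        ws.refresh()
        return ws.log_likelihood()

    ws.refresh()
    lnl = ws.log_likelihood()
    internals = [n for n in tree.postorder() if not n.is_tip]
    for p in range(passes):
        prev = lnl
        for node in internals:
            lo = max(c.height for c in node.children) + config.bl_min
            hi = (node.parent.height - config.bl_min) if node.parent is not None else lo + config.bl_max
            if hi <= lo:
                continue
            h0 = node.height
            current = lnl
            best_h, best_val = _maximize_1d(
                lambda h: lnl_with_height(node, h), lo, hi, h0, xatol=1e-10
            )
            if best_val > current:
                lnl = lnl_with_height(node, best_h)
            else:
                lnl = lnl_with_height(node, h0)  # restore pre-search state
        logger.debug("height sweep %d: lnL = %.6f", p + 1, lnl)
        if lnl - prev < config.tol_lnl:
            break
    return lnl


def optimize_clock_heights(tree, patterns, model, spec, config):
    """ML node heights on a fixed rooted topology; output is ultrametric.

    Returns ``(ultrametric_tree_copy, lnL)``.
    """
    if len(tree.root.children) != 2:
        raise ValueError("clock optimization requires a rooted (bifurcating-root) tree")
    tree = tree.copy()
    if any(n.height is None for n in tree.postorder()):
        _init_heights(tree)
    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    lnl = _clock_sweep(ws, tree, config, passes=config.max_passes)
    if not np.isfinite(lnl):
        raise ArithmeticError("non-finite likelihood during clock optimization")
    tree.set_lengths_from_heights()
    return tree, lnl


# ---------------------------------------------------------------------------
# topology search


def _copy_with_index(tree: PhyloTree) -> tuple[PhyloTree, list[TreeNode]]:
    """Copy a tree; also return the copy's postorder node list (the postorder
    index is the stable node identifier used when editing candidates)."""
    new = tree.copy()
    return new, list(new.postorder())


def _insert_tip_on_edge(node: TreeNode, name: str, pendant: float) -> TreeNode:
    """Split the branch above ``node`` and hang a new tip off the midpoint."""
    parent = node.parent
    joint = TreeNode()
    joint.length = node.length / 2.0
    parent.children[parent.children.index(node)] = joint
    joint.parent = parent
    node.length = node.length / 2.0
    joint.add_child(node)
    tip = joint.add_child(TreeNode(name, pendant))
    return tip


def infer_tree(aln: Alignment, config: InferenceConfig) -> tuple[PhyloTree, float]:
    """Full ML tree search on an alignment.

    Stepwise addition in seeded random order, then NNI sweeps, then a final
    full optimization of branch lengths (or node heights in clock mode).
    Deterministic for a fixed seed; ties are broken by the first-encountered
    candidate.
    """
    if aln.n_taxa < 3:
        raise ValueError("tree inference requires at least 3 taxa")
    spec = config.declared_error
    spec.validate_taxa(aln.taxon_names)
    model = build_model(config.ts_tv_ratio)
    rng = np.random.default_rng(config.seed)
    order = [aln.taxon_names[i] for i in rng.permutation(aln.n_taxa)]
    if config.clock:
        return _infer_clock(aln, order, model, spec, config)
    return _infer_nonclock(aln, order, model, spec, config)


def _infer_nonclock(aln, order, model, spec, config) -> tuple[PhyloTree, float]:
    init_len = 0.1
    root = TreeNode()
    for name in order[:3]:
        root.add_child(TreeNode(name, init_len))
    tree = PhyloTree(root, rooted=False)
    patterns = compress_patterns(aln.subset(order[:3]))
    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    _optimize_edges(ws, [n for n in tree.postorder() if n.parent], config, config.max_passes)

    for step, name in enumerate(order[3:], start=4):
        names = order[:step]
        patterns = compress_patterns(aln.subset(names))
        best = None
        n_edges = sum(1 for n in tree.postorder() if n.parent is not None)
        for edge_idx in range(n_edges):
            cand, nodes = _copy_with_index(tree)
            target = [n for n in nodes if n.parent is not None][edge_idx]
            tip = _insert_tip_on_edge(target, name, init_len)
            cand_ws = LikelihoodWorkspace(cand, patterns, model, spec)
            local = [tip, target, tip.parent]
            lnl = _optimize_edges(cand_ws, local, config, passes=2, xatol=1e-7)
            if best is None or lnl > best[0]:
                best = (lnl, cand)
        tree = best[1]
        ws = LikelihoodWorkspace(tree, patterns, model, spec)
        _optimize_edges(ws, [n for n in tree.postorder() if n.parent], config, passes=2)
        logger.debug("added %s (%d taxa): lnL = %.6f", name, step, tree.n_tips)

    patterns = compress_patterns(aln.subset(order))
    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    lnl = _optimize_edges(ws, [n for n in tree.postorder() if n.parent], config, config.max_passes)

    # NNI sweeps
    improved = True
    guard = 0
    while improved and guard < 50:
        improved = False
        guard += 1
        edges = [n for n in tree.postorder() if n.parent is not None]
        internal_idx = [i for i, n in enumerate(edges) if not n.is_tip]
        for idx in internal_idx:
            for alt in (0, 1):
                cand, nodes = _copy_with_index(tree)
                cedges = [n for n in nodes if n.parent is not None]
                u = cedges[idx]
                p = u.parent
                siblings = [c for c in p.children if c is not u]
                x = siblings[0]
                moved = u.children[alt]
                # swap subtree `moved` (child of u) with `x` (child of p)
                p.children[p.children.index(x)] = moved
                u.children[u.children.index(moved)] = x
                moved.parent, x.parent = p, u
                cand_ws = LikelihoodWorkspace(cand, patterns, model, spec)
                local = [u, x, moved]
                cand_lnl = _optimize_edges(cand_ws, local, config, passes=2, xatol=1e-7)
                if cand_lnl > lnl + config.tol_lnl:
                    tree = cand
                    ws = LikelihoodWorkspace(tree, patterns, model, spec)
                    lnl = _optimize_edges(
                        ws, [n for n in tree.postorder() if n.parent], config, passes=2
                    )
                    improved = True
                    break
            if improved:
                break

    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    lnl = _optimize_edges(ws, [n for n in tree.postorder() if n.parent], config, config.max_passes)
    logger.debug("final lnL = %.6f", lnl)
    return tree, lnl


def _infer_clock(aln, order, model, spec, config) -> tuple[PhyloTree, float]:
    patterns = compress_patterns(aln.subset(order[:3]))

    def three_taxon(a: str, b: str, c: str) -> PhyloTree:
        root = TreeNode()
        inner = root.add_child(TreeNode())
        inner.add_child(TreeNode(a))
        inner.add_child(TreeNode(b))
        root.add_child(TreeNode(c))
        for tip in (n for n in root.children[0].children):
            tip.length = 0.05
        inner.length = 0.05
        root.children[1].length = 0.1
        tree = PhyloTree(root, rooted=True)
        _init_heights(tree)
        return tree

    a, b, c = order[:3]
    best = None
    for tri in ((a, b, c), (a, c, b), (b, c, a)):
        cand = three_taxon(*tri)
        cand, lnl = optimize_clock_heights(cand, patterns, model, spec, config)
        if best is None or lnl > best[0]:
            best = (lnl, cand)
    lnl, tree = best

    for step, name in enumerate(order[3:], start=4):
        names = order[:step]
        patterns = compress_patterns(aln.subset(names))
        best = None
        n_nodes = sum(1 for n in tree.postorder() if n.parent is not None)
        # candidate placements: every existing branch, plus above the root
        for edge_idx in range(n_nodes + 1):
            cand, nodes = _copy_with_index(tree)
            if edge_idx < n_nodes:
                target = [n for n in nodes if n.parent is not None][edge_idx]
                joint = TreeNode()
                parent = target.parent
                joint.height = (parent.height + target.height) / 2.0
                parent.children[parent.children.index(target)] = joint
                joint.parent = parent
                joint.add_child(target)
                tip = joint.add_child(TreeNode(name))
                tip.height = 0.0
            else:
                old_root = cand.root
                new_root = TreeNode()
                new_root.height = old_root.height * 1.5 + 1e-6
                new_root.add_child(old_root)
                tip = new_root.add_child(TreeNode(name))
                tip.height = 0.0
                cand = PhyloTree(new_root, rooted=True)
            cand.set_lengths_from_heights()
            cand_ws = LikelihoodWorkspace(cand, patterns, model, spec)
            cand_lnl = _clock_sweep(cand_ws, cand, config, passes=2)
            if best is None or cand_lnl > best[0]:
                best = (cand_lnl, cand)
        lnl, tree = best
        logger.debug("added %s (clock, %d taxa): lnL = %.6f", name, step, lnl)

    patterns = compress_patterns(aln.subset(order))
    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    lnl = _clock_sweep(ws, tree, config, passes=config.max_passes)

    # rooted NNI
    improved = True
    guard = 0
    while improved and guard < 50:
        improved = False
        guard += 1
        edges = [n for n in tree.postorder() if n.parent is not None]
        internal_idx = [i for i, n in enumerate(edges) if not n.is_tip]
        for idx in internal_idx:
            for alt in (0, 1):
                cand, nodes = _copy_with_index(tree)
                cedges = [n for n in nodes if n.parent is not None]
                u = cedges[idx]
                p = u.parent
                x = [c for c in p.children if c is not u][0]
                moved = u.children[alt]
                p.children[p.children.index(x)] = moved
                u.children[u.children.index(moved)] = x
                moved.parent, x.parent = p, u
                floor = max(c.height for c in u.children)
                if floor >= p.height - 2 * config.bl_min:
                    continue
                if u.height <= floor:
                    u.height = (floor + p.height) / 2.0
                cand.set_lengths_from_heights()
                cand_ws = LikelihoodWorkspace(cand, patterns, model, spec)
                cand_lnl = _clock_sweep(cand_ws, cand, config, passes=2)
                if cand_lnl > lnl + config.tol_lnl:
                    tree = cand
                    ws = LikelihoodWorkspace(tree, patterns, model, spec)
                    lnl = _clock_sweep(ws, tree, config, passes=2)
                    improved = True
                    break
            if improved:
                break

    ws = LikelihoodWorkspace(tree, patterns, model, spec)
    lnl = _clock_sweep(ws, tree, config, passes=config.max_passes)
    tree.set_lengths_from_heights()
    logger.debug("final clock lnL = %.6f", lnl)
    return tree, lnl
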