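"""Pruning (peeling) computation of alignment log-likelihood on a tree.

Conditional likelihood 4-vectors are propagated from the tips to the root
under the K2P model with uniform root frequencies (1/4 each).  Tip vectors
come from the sequencing-error model, so a declared miscall rate enters the
likelihood only through the tip values.  Per-pattern renormalization with
accumulated log factors keeps the computation stable for large trees and
long alignments.

The workspace also exposes, for any branch, the likelihood as a function of
that branch's length with everything else held fixed (the standard
"two-subtree" factorization), which is what the branch-length optimizer
iterates over.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .errormodel import ErrorSpec, tip_vector
from .phylotree import PhyloTree, TreeNode
from .seqio import SitePatterns
from .substmodel import SubstModel, transition_matrix

PI = np.full(4, 0.25)

_LOG_FLOOR = 1e-300


class LikelihoodWorkspace:
    """Per-tree, per-alignment pruning state.

    Rebuild the workspace after a topology change; branch-length changes only
    require :meth:`refresh`.
    """

    def __init__(
        self,
        tree: PhyloTree,
        patterns: SitePatterns,
        model: SubstModel,
        spec: ErrorSpec,
    ):
        tip_names = set(tree.tip_names())
        if tip_names != set(patterns.taxon_names):
            raise ValueError(
                "tree tips and alignment taxa differ "
                f"(tree only: {sorted(tip_names - set(patterns.taxon_names))}, "
                f"alignment only: {sorted(set(patterns.taxon_names) - tip_names)})"
            )
        spec.validate_taxa(patterns.taxon_names)
        self.tree = tree
        self.patterns = patterns
        self.model = model
        self.spec = spec
        self.weights = patterns.weights.astype(float)

        # per-taxon column of every pattern
        taxon_index = {name: i for i, name in enumerate(patterns.taxon_names)}
        self._tip_partials: dict[int, np.ndarray] = {}
        for tip in tree.tips():
            i = taxon_index[tip.name]
            symbols = [p[i] for p in patterns.patterns]
            eps = spec.rate_for(tip.name)
            cache = {s: tip_vector(s, eps) for s in set(symbols)}
            self._tip_partials[id(tip)] = np.array([cache[s] for s in symbols], dtype=float)

        self._post: list[TreeNode] = list(tree.postorder())
        self._D: dict[int, np.ndarray] = {}
        self._dlog: dict[int, np.ndarray] = {}
        self._M: dict[int, np.ndarray] = {}
        self._B: dict[int, np.ndarray] = {}
        self._blog: dict[int, np.ndarray] = {}
        self._outside_current = False
        self.refresh()

    # -- core passes -------------------------------------------------------

    def refresh(self) -> None:
        """Recompute the tip-to-root (postorder) pass for current lengths."""
        D, dlog, M = self._D, self._dlog, self._M
        for node in self._post:
            if node.is_tip:
                d = self._tip_partials[id(node)]
                dl = np.zeros(len(self.weights))
            else:
                d = None
                dl = np.zeros(len(self.weights))
                for child in node.children:
                    m = D[id(child)] @ transition_matrix(self.model, child.length).T
                    M[id(child)] = m
                    d = m if d is None else d * m
                    dl = dl + dlog[id(child)]
                scale = d.max(axis=1)
                scale[scale <= 0.0] = 1.0
                d = d / scale[:, None]
                dl = dl + np.log(scale)
            D[id(node)] = d
            dlog[id(node)] = dl
        self._outside_current = False

    def log_likelihood(self) -> float:
        """Natural-log likelihood, summed over weighted site patterns."""
        root = self.tree.root
        v = self._D[id(root)] @ PI
        return float(
            np.dot(self.weights, np.log(np.maximum(v, _LOG_FLOOR)) + self._dlog[id(root)])
        )

    def _compute_outside(self) -> None:
        """Root-to-tip pass: for each non-root node u, the likelihood of all
        data outside u's subtree as a function of the state at u's parent."""
        B, blog, D, dlog, M = self._B, self._blog, self._D, self._dlog, self._M
        out: dict[int, np.ndarray] = {id(self.tree.root): np.tile(PI, (len(self.weights), 1))}
        olog: dict[int, np.ndarray] = {id(self.tree.root): np.zeros(len(self.weights))}
        for node in self.tree.preorder():
            for child in node.children:
                b = out[id(node)].copy()
                bl = olog[id(node)].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    b *= M[id(sib)]
                    bl += dlog[id(sib)]
                scale = b.max(axis=1)
                scale[scale <= 0.0] = 1.0
                b /= scale[:, None]
                bl += np.log(scale)
                B[id(child)], blog[id(child)] = b, bl
                if child.children:
                    out[id(child)] = b @ transition_matrix(self.model, child.length)
                    olog[id(child)] = bl
        self._outside_current = True

    # -- branch-length machinery ------------------------------------------

    def edge_objective(self, node: TreeNode) -> Callable[[float], float]:
        """lnL as a function of the length of the branch above ``node``.

        Valid until any branch length or the topology changes.
        """
        if node.parent is None:
            raise ValueError("the root has no branch")
        if not self._outside_current:
            self._compute_outside()
        b_vec = self._B[id(node)]
        d_vec = self._D[id(node)]
        const = self._blog[id(node)] + self._dlog[id(node)]
        weights = self.weights

        def lnl(branch_length: float) -> float:
            p = transition_matrix(self.model, branch_length)
            v = np.einsum("ij,jk,ik->i", b_vec, p, d_vec)
            return float(np.dot(weights, np.log(np.maximum(v, _LOG_FLOOR)) + const))

        return lnl


def log_likelihood(
    tree: PhyloTree, patterns: SitePatterns, model: SubstModel, spec: ErrorSpec
) -> float:
    """Pruning log-likelihood of the site patterns on the tree."""
    value = LikelihoodWorkspace(tree, patterns, model, spec).log_likelihood()
    if not np.isfinite(value):
        raise ArithmeticError("non-finite log-likelihood (numerical failure)")
    return value
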