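import math

import numpy as np
import pytest

from phyloerr.errormodel import ErrorSpec
from phyloerr.inference import (
    InferenceConfig,
    infer_tree,
    k2p_distance,
    ml_pairwise_distance,
    optimize_branch_lengths,
    optimize_clock_heights,
)
from phyloerr.phylotree import PhyloTree, TreeNode, parse_newick, rf_distance, total_length
from phyloerr.seqio import Alignment, compress_patterns
from phyloerr.simulate import evolve_alignment, inject_errors, simulate_yule_tree
from phyloerr.substmodel import build_model


def _pair_alignment(n, n_ts, n_tv):
    s1 = "A" * n
    s2 = "A" * (n - n_ts - n_tv) + "G" * n_ts + "C" * n_tv
    return s1, s2


class TestPairwiseDistance:
    def test_identical_sequences(self, k2p):
        assert ml_pairwise_distance("ACGT" * 10, "ACGT" * 10, k2p, 0.0) == 0.0

    def test_closed_form_k2p(self, k2p):
        s1, s2 = _pair_alignment(1000, 100, 50)  # P=0.1, Q=0.05
        d = ml_pairwise_distance(s1, s2, k2p, 0.0)
        assert d == pytest.approx(0.1701812, abs=1e-6)
        assert d == pytest.approx(k2p_distance(0.1, 0.05), abs=1e-12)

    def test_error_model_absorbs_expected_miscalls(self, k2p):
        # mismatches exactly at the expected yield of eps=0.1 noise
        # P(visible mismatch) = 2*eps*(1-eps) + 2*eps^2/3 = 14/75 at eps=0.1;
        # n=2250 makes the per-class expected count an exact integer (140)
        eps, n, per = 0.1, 2250, 140
        s1 = "A" * n
        s2 = "A" * (n - 3 * per) + "C" * per + "G" * per + "T" * per
        d = ml_pairwise_distance(s1, s2, k2p, eps)
        assert d <= 1e-7

    def test_saturated_data_warns_and_caps(self, k2p):
        s1, s2 = _pair_alignment(100, 60, 30)
        with pytest.warns(UserWarning, match="saturated"):
            assert ml_pairwise_distance(s1, s2, k2p, 0.0) == 100.0

    def test_ambiguity_codes_rejected(self, k2p):
        with pytest.raises(ValueError, match="resolved"):
            ml_pairwise_distance("ACGN", "ACGT", k2p, 0.0)


class TestOptimizeBranchLengths:
    def test_two_taxon_equivalence_with_pairwise(self, k2p):
        # with the model ratio matched to the data, the fixed-ratio branch
        # optimum coincides with the profiled pairwise estimate
        s1, s2 = _pair_alignment(1000, 100, 50)
        d = ml_pairwise_distance(s1, s2, k2p, 0.0)
        bb = -0.25 * math.log(1 - 2 * 0.05)  # beta*b component
        ab = d - 2 * bb  # alpha*b component
        model = build_model(ab / (2 * bb))
        aln = Alignment(["x", "y"], [s1, s2])
        root = TreeNode()
        root.add_child(TreeNode("x", 0.05))
        root.add_child(TreeNode("y", 0.05))
        opt, _ = optimize_branch_lengths(
            PhyloTree(root), compress_patterns(aln), model, ErrorSpec(0.0), InferenceConfig()
        )
        assert total_length(opt) == pytest.approx(d, abs=1e-6)

    def test_recovers_branch_lengths_at_large_n(self, k2p):
        true = parse_newick("((A:0.08,B:0.12):0.06,(C:0.1,D:0.15):0.04);")
        aln = evolve_alignment(true, k2p, 100_000, 202)
        start = true.copy()
        for node in start.postorder():
            if node.parent is not None:
                node.length = 0.05
        opt, lnl = optimize_branch_lengths(
            start, compress_patterns(aln), k2p, ErrorSpec(0.0), InferenceConfig()
        )
        got = {n.name: n.length for n in opt.postorder() if n.is_tip}
        want = {n.name: n.length for n in true.postorder() if n.is_tip}
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=0.05)

    def test_identical_sequences_collapse_to_bl_min(self, k2p):
        aln = Alignment(["a", "b", "c"], ["ACGT" * 25] * 3)
        root = TreeNode()
        for n in "abc":
            root.add_child(TreeNode(n, 0.1))
        config = InferenceConfig()
        opt, _ = optimize_branch_lengths(
            PhyloTree(root, rooted=False), compress_patterns(aln), k2p, ErrorSpec(0.0), config
        )
        for node in opt.postorder():
            if node.parent is not None:
                assert node.length <= config.bl_min * 10

    def test_lnl_never_decreases_across_sweeps(self, k2p, rng):
        tree = simulate_yule_tree(6, 1e-2, rng)
        aln = evolve_alignment(tree, k2p, 500, rng)
        start = tree.copy()
        for node in start.postorder():
            if node.parent is not None:
                node.length = 0.01
        from phyloerr.likelihood import log_likelihood

        pats = compress_patterns(aln)
        before = log_likelihood(start, pats, k2p, ErrorSpec(0.0))
        opt, lnl = optimize_branch_lengths(start, pats, k2p, ErrorSpec(0.0), InferenceConfig())
        assert lnl >= before


class TestOptimizeClockHeights:
    def test_two_taxon_root_height_is_half_distance(self, k2p):
        s1, s2 = _pair_alignment(2000, 100, 50)
        # matched-ratio model, as in the pairwise equivalence
        d = ml_pairwise_distance(s1, s2, k2p, 0.0)
        bb = -0.25 * math.log(1 - 2 * 50 / 2000)  # beta*b at Q = 0.025
        model = build_model((d - 2 * bb) / (2 * bb))
        aln = Alignment(["x", "y"], [s1, s2])
        root = TreeNode()
        root.add_child(TreeNode("x", 0.05))
        root.add_child(TreeNode("y", 0.05))
        opt, _ = optimize_clock_heights(
            PhyloTree(root), compress_patterns(aln), model, ErrorSpec(0.0), InferenceConfig(clock=True)
        )
        assert opt.root.height == pytest.approx(d / 2, rel=1e-4)

    def test_output_ultrametric_on_random_inputs(self, k2p, rng):
        tree = simulate_yule_tree(6, 1e-2, rng)
        aln = evolve_alignment(tree, k2p, 300, rng)
        start = tree.copy()
        opt, _ = optimize_clock_heights(
            start, compress_patterns(aln), k2p, ErrorSpec(0.0), InferenceConfig(clock=True)
        )
        assert opt.is_ultrametric(1e-6)

    def test_recovers_heights_at_large_n(self, k2p):
        true = simulate_yule_tree(4, 0.2, 55)
        aln = evolve_alignment(true, k2p, 100_000, 56)
        start = true.copy()
        opt, _ = optimize_clock_heights(
            start, compress_patterns(aln), k2p, ErrorSpec(0.0), InferenceConfig(clock=True)
        )
        assert opt.root.height == pytest.approx(true.root.height, rel=0.05)


class TestInferTree:
    def test_recovers_strong_signal_topology(self, k2p):
        true = parse_newick("((A:0.05,B:0.05):0.2,(C:0.05,D:0.05):0.2);")
        aln = evolve_alignment(true, k2p, 5000, 77)
        tree, _ = infer_tree(aln, InferenceConfig(seed=1))
        assert rf_distance(tree, true) == 0

    def test_deterministic_given_seed(self, k2p, rng):
        true = simulate_yule_tree(6, 1e-2, rng)
        aln = evolve_alignment(true, k2p, 400, rng)
        from phyloerr.phylotree import write_newick

        t1, l1 = infer_tree(aln, InferenceConfig(seed=42))
        t2, l2 = infer_tree(aln, InferenceConfig(seed=42))
        assert write_newick(t1) == write_newick(t2)
        assert l1 == l2

    def test_pure_noise_with_true_declared_error_collapses(self, rng):
        # declared = true epsilon: essentially all variable sites read as error
        clean = Alignment([f"t{i+1}" for i in range(6)], ["ACGT" * 100] * 6)
        noisy = inject_errors(clean, ErrorSpec(0.2), rng)
        corrected, _ = infer_tree(noisy, InferenceConfig(seed=3, declared_error=ErrorSpec(0.2)))
        uncorrected, _ = infer_tree(noisy, InferenceConfig(seed=3, declared_error=ErrorSpec(0.0)))
        # the correction absorbs the noise: tree shrinks by orders of magnitude
        assert total_length(corrected) < total_length(uncorrected) / 10.0
        assert total_length(corrected) < 0.2

    def test_total_length_non_increasing_in_declared_error(self, k2p, rng):
        true = simulate_yule_tree(5, 1e-3, rng)
        aln = inject_errors(evolve_alignment(true, k2p, 1000, rng), ErrorSpec(0.05), rng)
        lengths = [
            total_length(infer_tree(aln, InferenceConfig(seed=9, declared_error=ErrorSpec(e)))[0])
            for e in (0.0, 0.05, 0.2)
        ]
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_too_few_taxa_rejected(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError, match="3 taxa"):
            infer_tree(aln, InferenceConfig(seed=0))

    def test_clock_inference_recovers_ultrametric_topology(self, k2p):
        true = simulate_yule_tree(5, 0.05, 5)
        aln = evolve_alignment(true, k2p, 3000, 6)
        tree, _ = infer_tree(aln, InferenceConfig(seed=2, clock=True))
        assert tree.is_ultrametric(1e-6)
        assert rf_distance(tree, true) == 0


class TestInferenceConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            InferenceConfig(bl_min=0.0)
        with pytest.raises(ValueError):
            InferenceConfig(bl_min=1.0, bl_max=0.5)
        with pytest.raises(ValueError):
            InferenceConfig(tol_lnl=0.0)
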