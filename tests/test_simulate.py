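import numpy as np
import pytest

from phyloerr.errormodel import ErrorSpec
from phyloerr.phylotree import total_length
from phyloerr.seqio import Alignment, snp_density
from phyloerr.simulate import (
    SimulationConfig,
    bernoulli_snp_alignment,
    evolve_alignment,
    inject_errors,
    simulate_yule_tree,
)
from phyloerr.substmodel import TRANSITION_PARTNER, transition_matrix


class TestYuleTree:
    def test_shape_and_ultrametricity(self, rng):
        for n in (2, 3, 10, 20):
            t = simulate_yule_tree(n, 1e-3, rng)
            assert t.n_tips == n
            assert t.rooted
            assert t.is_ultrametric(1e-12)

    def test_rootmost_interval_mean_is_half_t(self):
        # with 2 lineages the split rate is 2/t, so the expected wait is t/2
        t_scale = 1e-3
        heights = [simulate_yule_tree(2, t_scale, s).root.height for s in range(4000)]
        se = np.std(heights) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - t_scale / 2) < 3 * se

    def test_mean_total_length(self):
        # n-1 inter-split intervals each contribute k * Exp(k/t), expectation t
        totals = [total_length(simulate_yule_tree(20, 1e-3, s)) for s in range(2000)]
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 19e-3) < 3 * se

    def test_interval_durations_are_exponential(self):
        # k-lineage interval ~ Exp(k/t): Kolmogorov-Smirnov on the 2-lineage wait
        from scipy.stats import kstest

        t_scale = 0.5
        waits = [simulate_yule_tree(2, t_scale, s).root.height for s in range(3000)]
        stat = kstest(waits, "expon", args=(0, t_scale / 2))
        assert stat.pvalue > 1e-3

    def test_deterministic_per_seed(self):
        from phyloerr.phylotree import write_newick

        a = simulate_yule_tree(10, 1e-2, 123)
        b = simulate_yule_tree(10, 1e-2, 123)
        assert write_newick(a) == write_newick(b)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 1e-3, 0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, 0.0, 0)


class TestEvolveAlignment:
    def test_zero_branches_copy_root(self, k2p, rng):
        t = simulate_yule_tree(5, 1e-3, rng)
        for node in t.postorder():
            if node.parent is not None:
                node.length = 0.0
        aln = evolve_alignment(t, k2p, 100, rng)
        assert len(set(aln.sequences)) == 1

    def test_single_branch_frequencies_match_transition_matrix(self, k2p):
        from phyloerr.phylotree import PhyloTree, TreeNode

        b = 0.5
        root = TreeNode()
        root.add_child(TreeNode("x", 0.0))
        root.add_child(TreeNode("y", b))
        aln = evolve_alignment(PhyloTree(root), k2p, 200_000, 99)
        p = transition_matrix(k2p, b)
        s1, s2 = aln.sequences
        for i, x in enumerate("ACGT"):
            xs = [s2[j] for j in range(len(s1)) if s1[j] == x]
            n = len(xs)
            for k, y in enumerate("ACGT"):
                freq = xs.count(y) / n
                se = np.sqrt(p[i, k] * (1 - p[i, k]) / n)
                assert abs(freq - p[i, k]) < 4 * se

    def test_transition_transversion_ratio_on_short_branch(self, k2p):
        from phyloerr.phylotree import PhyloTree, TreeNode

        root = TreeNode()
        root.add_child(TreeNode("x", 0.0))
        root.add_child(TreeNode("y", 0.02))
        aln = evolve_alignment(PhyloTree(root), k2p, 500_000, 7)
        s1, s2 = aln.sequences
        idx = {b: i for i, b in enumerate("ACGT")}
        ts = tv = 0
        for a, b in zip(s1, s2):
            if a == b:
                continue
            if idx[b] == TRANSITION_PARTNER[idx[a]]:
                ts += 1
            else:
                tv += 1
        assert ts / tv == pytest.approx(2.0, rel=0.15)

    def test_deterministic_per_seed(self, k2p, rng):
        t = simulate_yule_tree(5, 1e-2, 11)
        assert evolve_alignment(t, k2p, 50, 12).sequences == evolve_alignment(t, k2p, 50, 12).sequences


class TestInjectErrors:
    def test_zero_rate_is_identity(self, rng):
        aln = bernoulli_snp_alignment(5, 500, 0.2, rng)
        assert inject_errors(aln, ErrorSpec(0.0), rng).sequences == aln.sequences

    def test_changed_fraction_matches_epsilon(self, rng):
        aln = Alignment([f"t{i}" for i in range(10)], ["A" * 5000] * 10)
        out = inject_errors(aln, ErrorSpec(0.1), rng)
        changed = sum(c != "A" for s in out.sequences for c in s)
        n = 10 * 5000
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(changed / n - 0.1) < 4 * se

    def test_segregating_fraction_constant_alignment(self, rng):
        # a constant site stays constant iff no taxon is miscalled there
        n_taxa, eps = 20, 0.1
        aln = Alignment([f"t{i}" for i in range(n_taxa)], ["A" * 20_000] * n_taxa)
        out = inject_errors(aln, ErrorSpec(eps), rng)
        expected = 1 - (1 - eps) ** n_taxa
        frac = snp_density(out) / 1000
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(frac - expected) < 4 * se

    def test_per_taxon_rates(self, rng):
        aln = Alignment(["clean", "noisy"], ["A" * 4000] * 2)
        out = inject_errors(aln, ErrorSpec(0.0, {"noisy": 0.2}), rng)
        assert out.sequences[0] == "A" * 4000
        assert sum(c != "A" for c in out.sequences[1]) > 0

    def test_ambiguity_codes_rejected(self, rng):
        aln = Alignment(["a", "b"], ["ACGN", "ACGT"])
        with pytest.raises(ValueError, match="resolved"):
            inject_errors(aln, ErrorSpec(0.1), rng)


class TestBernoulliSnpAlignment:
    def test_extremes(self, rng):
        assert snp_density(bernoulli_snp_alignment(5, 300, 0.0, rng)) == 0.0
        assert snp_density(bernoulli_snp_alignment(5, 300, 1.0, rng)) == 1000.0

    def test_density_tracks_m(self, rng):
        m = 0.0472
        vals = [snp_density(bernoulli_snp_alignment(20, 20_000, m, rng)) for _ in range(5)]
        assert np.mean(vals) == pytest.approx(1000 * m, rel=0.05)

    def test_composition_with_error_injection(self, rng):
        # segregating fraction of (Bernoulli fixture + errors) follows
        # 1 - (1-m)(1-eps)^n up to tiny reversion terms
        m, eps, n = 0.05, 0.01, 20
        vals = []
        for _ in range(10):
            aln = bernoulli_snp_alignment(n, 20_000, m, rng)
            vals.append(snp_density(inject_errors(aln, ErrorSpec(eps), rng)))
        expected = 1000 * (1 - (1 - m) * (1 - eps) ** n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.02)


class TestSimulationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=2)
        with pytest.raises(ValueError):
            SimulationConfig(t=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_replicates=0)
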