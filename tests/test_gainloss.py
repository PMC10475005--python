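"""Gillespie feature gain/loss and the exact expected-FD recursion."""

import math

import numpy as np
import pytest

from featdiv import (
    BDParams,
    FeatureParams,
    evolve_features,
    expected_fd_tree,
    fd_of_run,
    prune_fob,
    read_newick,
    simulate_bd_tree,
    singleton_count,
)

from conftest import caterpillar_with_long_pendant, random_ultrametric_newick


def t2_expected_full(r, nu, l0, l):
    """Printed closed form for the two-leaf tree, all leaves kept."""
    g = lambda x: (r / nu) * (1.0 - math.exp(-nu * x))
    return g(l0) * (1.0 - (1.0 - math.exp(-nu * l)) ** 2) + 2.0 * g(l)


def t2_expected_pruned(r, nu, l0, l, s):
    """Printed closed form after a field-of-bullets event with survival s."""
    g = lambda x: (r / nu) * (1.0 - math.exp(-nu * x))
    full = t2_expected_full(r, nu, l0, l)
    return s * s * full + 2 * s * (1 - s) * (g(l0) * math.exp(-nu * l) + g(l))


class TestEvolveFeatures:
    def test_no_gain_no_root_features_empty(self, t2_tree):
        lf = evolve_features(t2_tree, FeatureParams(r=0.0, nu=0.5, f0=0), seed=1)
        assert all(len(v) == 0 for v in lf.features.values())

    def test_deterministic_under_seed(self, t2_tree):
        a = evolve_features(t2_tree, FeatureParams(0.7, 0.2, 2), seed=5)
        b = evolve_features(t2_tree, FeatureParams(0.7, 0.2, 2), seed=5)
        assert a.features == b.features

    def test_root_features_distinguishable(self):
        tree = read_newick("a:0.001;")
        lf = evolve_features(tree, FeatureParams(r=0.0, nu=0.0, f0=3), seed=1)
        assert lf.features["a"] == {"root0", "root1", "root2"}

    def test_extinct_leaves_excluded_from_output(self):
        tree = read_newick("(a:2,(b:0.5,c:1):1):0.5;")  # b extinct
        lf = evolve_features(tree, FeatureParams(1.0, 0.0, 0), seed=2)
        assert set(lf.features) == {"a", "c"}

    def test_single_edge_poisson_mean_and_dispersion(self):
        r, nu, ell, reps = 0.8, 0.4, 3.0, 10**4
        tree = read_newick(f"a:{ell};")
        mean = (r / nu) * (1.0 - math.exp(-nu * ell))
        counts = np.array([
            len(evolve_features(tree, FeatureParams(r, nu), seed=k).features["a"])
            for k in range(reps)
        ])
        se = math.sqrt(mean / reps)  # Poisson variance = mean
        assert abs(counts.mean() - mean) < 3 * se
        # index of dispersion: (n-1) s^2 / xbar ~ chi^2_{n-1} under Poisson
        d = (reps - 1) * counts.var(ddof=1) / counts.mean()
        assert abs(d - (reps - 1)) < 3 * math.sqrt(2 * (reps - 1))

    def test_tree_wide_fd_is_poisson_dispersed(self, rng):
        # total FD over the leaves of a fixed tree, started empty, is Poisson
        tree = read_newick(random_ultrametric_newick(rng, 6, age=2.0))
        reps = 10**4
        fp = FeatureParams(r=1.2, nu=0.6)
        vals = np.array([
            fd_of_run(evolve_features(tree, fp, seed=k)) for k in range(reps)
        ])
        d = (reps - 1) * vals.var(ddof=1) / vals.mean()
        assert abs(d - (reps - 1)) < 3 * math.sqrt(2 * (reps - 1))


class TestFdOfRunAndSingletons:
    def test_union_and_survivor_union(self, t2_tree):
        lf = evolve_features(t2_tree, FeatureParams(1.0, 0.1), seed=3)
        manual = set(lf.features["a"]) | set(lf.features["b"])
        assert fd_of_run(lf) == len(manual)
        assert fd_of_run(lf, ["a"]) == len(lf.features["a"])
        assert fd_of_run(lf, []) == 0

    def test_unknown_leaf_rejected(self, t2_tree):
        lf = evolve_features(t2_tree, FeatureParams(1.0, 0.1), seed=3)
        with pytest.raises(KeyError, match="nope"):
            fd_of_run(lf, ["nope"])

    def test_singletons_against_incidence_histogram(self, rng):
        tree = read_newick(random_ultrametric_newick(rng, 8, age=2.0))
        for k in range(10):
            lf = evolve_features(tree, FeatureParams(1.5, 0.5), seed=100 + k)
            hist = {}
            for fs in lf.features.values():
                for f in fs:
                    hist[f] = hist.get(f, 0) + 1
            assert singleton_count(lf) == sum(1 for v in hist.values() if v == 1)

    def test_disjoint_and_universal_features(self):
        from featdiv.gainloss import LeafFeatures

        lf = LeafFeatures({"a": frozenset({"x"}), "b": frozenset({"y"})}, 0)
        assert singleton_count(lf) == 2
        lf2 = LeafFeatures({"a": frozenset({"x"}), "b": frozenset({"x"})}, 0)
        assert singleton_count(lf2) == 0


class TestExpectedFdTree:
    @pytest.mark.parametrize("r", [0.1, 0.3, 1.0])
    @pytest.mark.parametrize("nu", [0.05, 0.4, 2.0])
    def test_two_leaf_closed_form_full(self, r, nu):
        for l0 in (0.2, 1.0, 3.0):
            for ell in (0.5, 1.5, 4.0):
                tree = read_newick(f"(a:{ell},b:{ell}):{l0};")
                got = expected_fd_tree(tree, FeatureParams(r, nu), s=1.0)
                want = t2_expected_full(r, nu, l0, ell)
                assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("s", [0.1, 0.5, 0.9])
    def test_two_leaf_closed_form_pruned(self, s):
        r, nu, l0, ell = 0.3, 0.6, 0.8, 1.2
        tree = read_newick(f"(a:{ell},b:{ell}):{l0};")
        got = expected_fd_tree(tree, FeatureParams(r, nu), s=s)
        assert got == pytest.approx(t2_expected_pruned(r, nu, l0, ell, s), rel=1e-12)

    def test_zero_loss_equals_r_times_total_length(self, rng):
        tree = read_newick(random_ultrametric_newick(rng, 7, age=1.5))
        r = 0.9
        exact0 = expected_fd_tree(tree, FeatureParams(r, 0.0), s=1.0)
        assert exact0 == pytest.approx(r * tree.total_branch_length(), rel=1e-12)
        # tiny nu approaches the nu = 0 branch
        near = expected_fd_tree(tree, FeatureParams(r, 1e-8), s=1.0)
        assert near == pytest.approx(exact0, rel=1e-6)

    def test_upper_bound_r_over_nu_times_n(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 10))
            tree = read_newick(random_ultrametric_newick(rng, n, age=3.0))
            r, nu, f0 = 1.0, 0.3, 4
            val = expected_fd_tree(tree, FeatureParams(r, nu, f0), s=1.0)
            assert val <= (r / nu) * n + f0 + 1e-9

    def test_pruned_ratio_decreasing_in_nu(self):
        # E[FD pruned]/E[FD full] on the two-leaf tree falls as loss speeds up
        l0, ell, s = 0.8, 1.2, 0.4
        ratios = []
        for nu in (0.05, 0.2, 0.8, 2.0, 5.0):
            full = t2_expected_full(0.3, nu, l0, ell)
            ratios.append(t2_expected_pruned(0.3, nu, l0, ell, s) / full)
        assert all(b < a for a, b in zip(ratios, ratios[1:]))

    def test_monte_carlo_agreement_random_trees(self, rng):
        reps = 3000
        for k in range(8):
            n = int(rng.integers(2, 13))
            tree = read_newick(random_ultrametric_newick(rng, n, age=2.0))
            fp = FeatureParams(r=1.0, nu=0.4, f0=int(rng.integers(0, 3)))
            s = float(rng.uniform(0.3, 1.0))
            exact = expected_fd_tree(tree, fp, s=s)
            labels = tree.extant_leaf_labels()
            vals = np.empty(reps)
            sub_rng = np.random.default_rng(5000 + k)
            for i in range(reps):
                lf = evolve_features(tree, fp, seed=int(sub_rng.integers(2**31)))
                keep = [lb for lb in labels if sub_rng.random() < s]
                vals[i] = fd_of_run(lf, keep)
            se = vals.std(ddof=1) / math.sqrt(reps)
            assert abs(vals.mean() - exact) < 3.5 * se, (n, fp, s)

    def test_long_pendant_ratio_never_concentrates(self):
        # variance of FD(survivors)/FD(all) stays high as n grows: the one
        # long-pendant leaf carries a non-vanishing share of all features
        fp = FeatureParams(r=2.0, nu=0.2)
        out = {}
        for n in (8, 64):
            tree = caterpillar_with_long_pendant(n, ell=2.0)
            labels = tree.extant_leaf_labels()
            ratios = []
            sub = np.random.default_rng(42)
            for i in range(400):
                lf = evolve_features(tree, fp, seed=int(sub.integers(2**31)))
                total = fd_of_run(lf)
                if total == 0:
                    continue
                keep = [lb for lb in labels if sub.random() < 0.5]
                ratios.append(fd_of_run(lf, keep) / total)
            out[n] = np.var(ratios)
        assert out[64] > 0.25 * out[8]
        assert out[64] > 0.005
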