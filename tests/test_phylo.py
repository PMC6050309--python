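import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repeatscape import phylo
from repeatscape.phylo import Phylogeny
from repeatscape.simulate import simulate_bm_traits
from repeatscape.types import NeSeries

from conftest import balanced_newick, random_newick


def _gls_machinery(tree: Phylogeny):
    """BM covariance matrix and shared-path helpers, built independently of
    the pruning code (direct path enumeration)."""
    depth = np.zeros(tree.n_nodes)
    for node in reversed(tree.postorder):
        for ch in tree.children[node]:
            depth[ch] = depth[node] + tree.branch_length[ch]
    ancestors = {}
    for i in range(tree.n_nodes):
        path = []
        j = i
        while j != -1:
            path.append(j)
            j = int(tree.parent[j])
        ancestors[i] = set(path)

    def shared(i, j):
        return max(depth[n] for n in ancestors[i] & ancestors[j])

    n = tree.n_tips
    V = np.array([[shared(i, j) if i != j else depth[i] for j in range(n)]
                  for i in range(n)])
    return V, shared, depth


class TestPicContrasts:
    def test_two_tip_closed_form(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        cs = phylo.pic_contrasts(t, {"A": 3.0, "B": 1.0})
        assert len(cs.contrasts) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(math.sqrt(2))

    def test_count_is_ntips_minus_one(self, rng):
        t = Phylogeny.from_newick(random_newick(rng, 17))
        traits = {l: float(i) for i, l in enumerate(t.tip_labels)}
        cs = phylo.pic_contrasts(t, traits)
        assert len(cs.contrasts) == 16

    def test_translation_invariance(self, rng):
        t = Phylogeny.from_newick(random_newick(rng, 10))
        traits = {l: float(rng.normal()) for l in t.tip_labels}
        shifted = {k: v + 42.0 for k, v in traits.items()}
        c1 = phylo.pic_contrasts(t, traits).contrasts
        c2 = phylo.pic_contrasts(t, shifted).contrasts
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_missing_tip_named_in_error(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            phylo.pic_contrasts(t, {"A": 1.0})

    def test_bm_contrasts_standardized(self):
        # under BM(sigma2), standardized contrasts are iid N(0, sigma2)
        t = Phylogeny.from_newick(balanced_newick(64))
        rng = np.random.default_rng(7)
        tips = phylo.simulate_bm_matrix(t, 2.5, 200, rng)
        u, _, _, _ = phylo._prune(t, tips)
        assert abs(u.mean()) < 0.05
        assert u.var() == pytest.approx(2.5, rel=0.1)
        # variance homogeneity across nodes (Bartlett over node rows)
        _, p = stats.bartlett(*[u[i] for i in range(0, 63, 7)])
        assert p > 0.001

    def test_polytomy_resolution(self):
        t = Phylogeny.from_newick("(A:1,B:1,C:1);")
        cs = phylo.pic_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert len(cs.contrasts) == 2


class TestPicRegression:
    def test_exact_linear(self, rng):
        x = rng.normal(size=20)
        reg = phylo.pic_regression(2 * x, x)
        assert reg.slope == pytest.approx(2.0)
        assert reg.p_value < 1e-12

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            phylo.pic_regression(np.ones(5), np.zeros(5))

    def test_type_i_calibration(self):
        t = Phylogeny.from_newick(balanced_newick(32))
        rng = np.random.default_rng(11)
        n_pairs = 1000
        xs = phylo.simulate_bm_matrix(t, 1.0, n_pairs, rng)
        ys = phylo.simulate_bm_matrix(t, 1.0, n_pairs, rng)
        ux, _, _, _ = phylo._prune(t, xs)
        uy, _, _, _ = phylo._prune(t, ys)
        rejections = sum(
            phylo.pic_regression(uy[:, i], ux[:, i]).p_value < 0.05
            for i in range(n_pairs)
        )
        assert 0.03 <= rejections / n_pairs <= 0.07

    def test_gls_equivalence_on_small_trees(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 13))
            t = Phylogeny.from_newick(random_newick(rng, n))
            x = {l: float(rng.normal()) for l in t.tip_labels}
            y = {l: float(rng.normal()) for l in t.tip_labels}
            cx = phylo.pic_contrasts(t, x).contrasts
            cy = phylo.pic_contrasts(t, y).contrasts
            slope = phylo.pic_regression(cy, cx).slope
            V, _, _ = _gls_machinery(t)
            Vi = np.linalg.inv(V)
            X = np.column_stack([np.ones(n), [x[l] for l in t.tip_labels]])
            yv = np.array([y[l] for l in t.tip_labels])
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
            assert slope == pytest.approx(beta[1], abs=1e-8)


class TestCensoredRateTest:
    def _tree_and_regimes(self, n=16):
        t = Phylogeny.from_newick(balanced_newick(n))
        regimes = {f"t{i}": ("A" if i < n // 2 else "B") for i in range(n)}
        return t, regimes

    def test_null_behavior(self):
        t, regimes = self._tree_and_regimes()
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(100):
            tips = phylo.simulate_bm_matrix(t, 1.0, 1, rng)
            traits = dict(zip(t.tip_labels, tips[:, 0]))
            res = phylo.censored_rate_test(t, traits, regimes, n_sims=200, seed=rep)
            ps.append(res.p_value)
        # p approximately uniform: KS test should not reject wildly
        assert stats.kstest(ps, "uniform").pvalue > 0.001
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_power_ratio_ten(self):
        t = Phylogeny.from_newick(balanced_newick(64))
        regimes = {f"t{i}": ("A" if i < 32 else "B") for i in range(64)}
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            traits = simulate_bm_traits(
                t, {"A": 1.0, "B": 10.0}, seed=900 + rep, tip_regimes=regimes
            )["trait"]
            res = phylo.censored_rate_test(
                t, traits.to_dict(), regimes, n_sims=200, seed=rep
            )
            if res.p_value < 0.05:
                rejections += 1
        assert rejections >= 0.8 * n_reps

    def test_single_regime_lr_zero(self):
        t, _ = self._tree_and_regimes()
        regimes = {f"t{i}": "A" for i in range(16)}
        traits = {l: float(i) for i, l in enumerate(t.tip_labels)}
        res = phylo.censored_rate_test(t, traits, regimes, n_sims=10, seed=0)
        assert res.lr_statistic == pytest.approx(0.0, abs=1e-10)

    def test_small_regime_error(self):
        t, _ = self._tree_and_regimes()
        regimes = {f"t{i}": ("A" if i > 0 else "B") for i in range(16)}
        traits = {l: float(i) for i, l in enumerate(t.tip_labels)}
        with pytest.raises(ValueError, match="fewer than 2"):
            phylo.censored_rate_test(t, traits, regimes, n_sims=10, seed=0)

    def test_tip_order_permutation_invariance(self):
        t, regimes = self._tree_and_regimes()
        traits = {f"t{i}": float(i**1.3) for i in range(16)}
        r1 = phylo.censored_rate_test(t, traits, regimes, n_sims=50, seed=5)
        shuffled = dict(reversed(list(traits.items())))
        r2 = phylo.censored_rate_test(t, shuffled, regimes, n_sims=50, seed=5)
        assert r1.lr_statistic == pytest.approx(r2.lr_statistic)


class TestAsrBm:
    def test_symmetric_mean(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        states = phylo.asr_bm(t, {"A": 3.0, "B": 1.0})
        assert list(states.values()) == [pytest.approx(2.0)]

    def test_constant_trait(self, rng):
        t = Phylogeny.from_newick(random_newick(rng, 8))
        states = phylo.asr_bm(t, {l: 5.5 for l in t.tip_labels})
        for v in states.values():
            assert v == pytest.approx(5.5)

    def test_matches_gls_closed_form(self, rng):
        for _ in range(5):
            t = Phylogeny.from_newick(random_newick(rng, 10))
            x = {l: float(rng.normal()) for l in t.tip_labels}
            states = phylo.asr_bm(t, x)
            V, shared, depth = _gls_machinery(t)
            Vi = np.linalg.inv(V)
            one = np.ones(t.n_tips)
            xv = np.array([x[l] for l in t.tip_labels])
            mu = (one @ Vi @ xv) / (one @ Vi @ one)
            for node, state in states.items():
                c = np.array([shared(node, j) for j in range(t.n_tips)])
                want = mu + c @ Vi @ (xv - mu * one)
                assert state == pytest.approx(want, abs=1e-8)

    def test_root_equals_pic_weighted_mean(self, rng):
        t = Phylogeny.from_newick(random_newick(rng, 12))
        x = {l: float(rng.normal()) for l in t.tip_labels}
        cs = phylo.pic_contrasts(t, x)
        states = phylo.asr_bm(t, x)
        assert states[t.root] == pytest.approx(cs.node_values[t.root, 0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, p = phylo.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_identical_groups(self):
        h, p = phylo.kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert h == 0.0
        assert p == 1.0

    def test_permutation_calibration(self, rng):
        data = rng.normal(size=30)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(data)
            ps.append(phylo.kruskal_wallis([perm[:10], perm[10:20], perm[20:]])[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestDunnBh:
    def test_identical_groups_adjusted_one(self):
        df = phylo.dunn_bh([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert (df["p_adjusted"] == 1.0).all()

    def test_bh_step_up_arithmetic(self):
        adjusted = phylo.benjamini_hochberg([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.03])

    def test_monotone_in_raw_p(self, rng):
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.4, 1.0, 2.0)]
        df = phylo.dunn_bh(groups).sort_values("p_raw")
        assert df["p_adjusted"].is_monotonic_increasing

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            phylo.dunn_bh([[1, 2], [3, 4]])


class TestGateAndTransform:
    def test_lognormal_gated_to_log(self, rng):
        x = np.exp(rng.normal(0, 1.5, size=200))
        report = phylo.gate_and_transform(x)
        assert report.scale == "log"
        assert report.shapiro_p_raw <= 0.05
        assert report.shapiro_p_log > 0.05

    def test_normal_passes_raw(self, rng):
        x = rng.normal(10, 1, size=200)
        report = phylo.gate_and_transform(x)
        assert report.scale == "raw"

    def test_constant_degenerate(self):
        report = phylo.gate_and_transform([3.0, 3.0, 3.0, 3.0])
        assert report.scale == "rank"

    def test_nonpositive_log_refused(self, rng):
        x = np.concatenate([[-1.0], np.exp(rng.normal(0, 2, size=100))])
        with pytest.raises(ValueError, match="non-positive"):
            phylo.gate_and_transform(x)


class TestMedianNe:
    def _series(self, ne, times=None):
        times = times or [1000.0 * (i + 1) for i in range(len(ne))]
        return NeSeries("sp", list(zip(times, ne)))

    def test_trim_endpoints(self):
        assert phylo.median_ne(self._series([10, 20, 30, 40, 50])) == 30

    def test_window_scheme(self):
        s = self._series(
            [1, 100, 1000, 9999], times=[10e3, 100e3, 1e6, 20e6]
        )
        assert phylo.median_ne(s, "window_20ky_10my") == pytest.approx(550.0)

    def test_schemes_agree_on_stationary_series(self, rng):
        ne = rng.uniform(9000, 11000, size=100)
        times = np.sort(rng.uniform(25e3, 9e6, size=100))
        s = NeSeries("sp", list(zip(times.tolist(), ne.tolist())))
        medians = [phylo.median_ne(s, sch) for sch in phylo.NE_SCHEMES]
        assert max(medians) / min(medians) < 1.1

    def test_empty_after_filter_error(self):
        s = self._series([10, 20, 30], times=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            phylo.median_ne(s, "window_20ky_10my")

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            phylo.median_ne(self._series([1, 2, 3]), "bogus")
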