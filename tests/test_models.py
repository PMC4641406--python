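import math

import numpy as np
import pytest

import phylotraits as pt
from phylotraits.models import bm_pruning_loglik, bm_unit_covariance
from conftest import random_tree_and_painting, random_spec
from oracles import joint_moments_oracle, mvn_logpdf


class TestTraitMoments:
    def test_bm_shared_path_covariance(self, cherry3):
        paint = pt.RegimeMap.single(cherry3)
        mu, V = pt.trait_moments(cherry3, paint,
                                 pt.ModelSpec("BM1", 1.0, x0=0.0))
        labels = cherry3.tip_labels
        iA, iB, iC = (labels.index(x) for x in "ABC")
        assert np.allclose(np.diag(V), 2.0)
        assert V[iA, iB] == pytest.approx(1.0)
        assert V[iA, iC] == pytest.approx(0.0)

    def test_ou_stationary_approach_variance(self, star3):
        paint = pt.RegimeMap.single(star3)
        spec = pt.ModelSpec("OU1", 2.0, alpha=1.0, theta=0.0)
        mu, V = pt.trait_moments(star3, paint, spec)
        expect = (1 - math.exp(-2.0)) * 1.0   # sigma^2(1-e^{-2aT})/(2a)
        assert np.allclose(np.diag(V), expect, atol=1e-10)
        assert np.allclose(V - np.diag(np.diag(V)), 0.0)
        assert np.allclose(mu, 0.0)   # root starts at theta

    def test_bms_per_edge_rates(self):
        t = pt.read_newick("(A:1,B:1);")
        # paint the two tip edges with different classes
        paint = pt.shift_branches_to_era_map(t, [2])
        spec = pt.ModelSpec("BMS", {"0": 1.0, "2": 4.0}, x0=0.0)
        mu, V = pt.trait_moments(t, paint, spec)
        assert sorted(np.diag(V)) == pytest.approx([1.0, 4.0])
        assert V[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize("family", pt.FAMILIES)
    def test_matches_joint_composition_oracle(self, family):
        rng = np.random.default_rng(hash(family) % 2 ** 31)
        for _ in range(15):
            tree, painting = random_tree_and_painting(rng)
            spec = random_spec(rng, family, painting.labels)
            mu, V = pt.trait_moments(tree, painting, spec)
            mu_o, V_o = joint_moments_oracle(tree, painting, spec)
            assert np.allclose(mu, mu_o, atol=1e-10)
            assert np.allclose(V, V_o, atol=1e-10)


class TestLoglik:
    def test_two_tip_star_standard_normals(self):
        t = pt.read_newick("(A:1,B:1);")
        paint = pt.RegimeMap.single(t)
        ll = pt.loglik(t, paint, pt.ModelSpec("BM1", 1.0, x0=0.0),
                       pt.TraitData({"A": 0.0, "B": 0.0}))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_data_at_mean_gives_det_term_only(self, five_tip):
        paint = pt.shift_branches_to_era_map(five_tip, [1])
        spec = pt.ModelSpec("OUMVA", {"0": 0.5, "1": 2.0},
                            alpha={"0": 2.0, "1": 0.5},
                            theta={"0": -1.0, "1": 1.0})
        mu, V = pt.trait_moments(five_tip, paint, spec)
        data = pt.TraitData(dict(zip(five_tip.tip_labels, mu)))
        ll = pt.loglik(five_tip, paint, spec, data)
        expect = -0.5 * (5 * math.log(2 * math.pi)
                         + np.linalg.slogdet(V)[1])
        assert ll == pytest.approx(expect, abs=1e-10)

    def test_singular_covariance_raises(self):
        t = pt.read_newick("(A:1,B:1);")
        paint = pt.RegimeMap.single(t)
        with pytest.raises(ValueError, match="singular"):
            pt.loglik(t, paint, pt.ModelSpec("BM1", 0.0, x0=0.0),
                      pt.TraitData({"A": 0.0, "B": 1.0}))

    def test_se_equals_explicit_diagonal_inflation(self, yule50):
        rng = np.random.default_rng(3)
        paint = pt.RegimeMap.single(yule50)
        spec = pt.ModelSpec("BM1", 1.3, x0=0.0)
        vals = dict(zip(yule50.tip_labels,
                        rng.normal(size=yule50.n_tips)))
        s = 0.4
        ll_se = pt.loglik(yule50, paint, spec,
                          pt.TraitData(vals, {l: s for l in vals}))
        mu, V = pt.trait_moments(yule50, paint, spec)
        x = np.array([vals[l] for l in yule50.tip_labels])
        ll_direct = mvn_logpdf(x, mu, 1.3 * bm_unit_covariance(yule50)
                               + s ** 2 * np.eye(len(x)))
        assert ll_se == pytest.approx(ll_direct, abs=1e-8)

    def test_invariant_to_tip_relabeling(self):
        nwk1 = "((A:1,B:1):1,(C:1,D:1):1);"
        nwk2 = "((C:1,D:1):1,(B:1,A:1):1);"
        vals = {"A": 0.3, "B": -0.2, "C": 1.4, "D": 0.9}
        for family, kw in [("BM1", dict(sigma2=1.2, x0=0.1)),
                           ("OU1", dict(sigma2=1.2, alpha=0.8, theta=0.2))]:
            l1 = pt.loglik(pt.read_newick(nwk1),
                           pt.RegimeMap.single(pt.read_newick(nwk1)),
                           pt.ModelSpec(family, **kw), pt.TraitData(vals))
            l2 = pt.loglik(pt.read_newick(nwk2),
                           pt.RegimeMap.single(pt.read_newick(nwk2)),
                           pt.ModelSpec(family, **kw), pt.TraitData(vals))
            assert l1 == pytest.approx(l2, abs=1e-10)


class TestFamilyLimits:
    def setup_method(self):
        self.tree = pt.yule_tree(20, seed=13)
        self.paint1 = pt.RegimeMap.single(self.tree)
        self.paint2 = pt.shift_branches_to_era_map(self.tree, [1])
        rng = np.random.default_rng(8)
        self.data = pt.TraitData(dict(zip(self.tree.tip_labels,
                                          rng.normal(size=20))))

    def test_ou1_to_bm1_alpha_limit(self):
        bm = pt.loglik(self.tree, self.paint1,
                       pt.ModelSpec("BM1", 1.5, x0=0.3), self.data)
        ou = pt.loglik(self.tree, self.paint1,
                       pt.ModelSpec("OU1", 1.5, alpha=1e-10, theta=0.3),
                       self.data)
        assert ou == pytest.approx(bm, abs=1e-6)

    def test_acdc_r0_equals_bm1(self):
        bm = pt.loglik(self.tree, self.paint1,
                       pt.ModelSpec("BM1", 1.5, x0=0.3), self.data)
        ac = pt.loglik(self.tree, self.paint1,
                       pt.ModelSpec("ACDC", 1.5, r=0.0, x0=0.3), self.data)
        assert ac == pytest.approx(bm, abs=1e-12)

    def test_oum_equal_theta_equals_ou1(self):
        ou1 = pt.loglik(self.tree, self.paint1,
                        pt.ModelSpec("OU1", 1.5, alpha=2.0, theta=0.4),
                        self.data)
        oum = pt.loglik(self.tree, self.paint2,
                        pt.ModelSpec("OUM", 1.5, alpha=2.0,
                                     theta={"0": 0.4, "1": 0.4}), self.data)
        assert oum == pytest.approx(ou1, abs=1e-12)


class TestFit:
    def test_bm1_sigma2_recovery_small(self):
        hits = 0
        for rep in range(10):
            ds = pt.make_recovery_dataset("BM1", {"sigma2": 1.0, "x0": 0.0},
                                          200, seed=rep)
            fr = pt.fit(ds.tree, ds.painting, "BM1", ds.data, n_starts=2)
            s2 = fr.spec.sigma2
            s2 = s2 if not isinstance(s2, dict) else s2["0"]
            if 0.8 <= s2 <= 1.2:
                hits += 1
        assert hits >= 8

    def test_ou1_on_bm_data_nests(self):
        ds = pt.make_recovery_dataset("BM1", {"sigma2": 1.0, "x0": 0.0},
                                      100, seed=3)
        bm = pt.fit(ds.tree, ds.painting, "BM1", ds.data)
        ou = pt.fit(ds.tree, ds.painting, "OU1", ds.data)
        assert ou.loglik >= bm.loglik - 1e-6

    def test_common_se_adds_parameter(self):
        ds = pt.make_recovery_dataset("BM1", {"sigma2": 1.0, "x0": 0.0},
                                      60, seed=5)
        f0 = pt.fit(ds.tree, ds.painting, "BM1", ds.data)
        f1 = pt.fit(ds.tree, ds.painting, "BM1", ds.data, se_mode="common")
        assert f1.k == f0.k + 1
        assert f1.loglik >= f0.loglik - 1e-6   # nested

    def test_too_few_tips_raises(self, star3):
        data = pt.TraitData({"A": 0.0, "B": 1.0, "C": 2.0})
        with pytest.raises(ValueError, match="few tips"):
            pt.fit(star3, pt.RegimeMap.single(star3), "OU1", data)


class TestAiccCompare:
    def test_closed_form(self):
        assert pt.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_weight_ratio(self):
        f = [pt.FitResult(pt.ModelSpec("BM1", 1.0, x0=0.0), 0, 2, 10, a)
             for a in (10.0, 12.0)]
        comp = pt.compare(f, names=["m1", "m2"])
        assert comp.weights[0] == pytest.approx(1 / (1 + math.exp(-1)),
                                                abs=1e-10)
        assert comp.weights[1] == pytest.approx(
            math.exp(-1) / (1 + math.exp(-1)), abs=1e-10)

    def test_equal_models_split_weight(self):
        f = [pt.FitResult(pt.ModelSpec("BM1", 1.0, x0=0.0), 0, 2, 10, 5.0)
             for _ in range(4)]
        comp = pt.compare(f)
        assert np.allclose(comp.weights, 0.25)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_adding_worse_model_keeps_ranking(self):
        mk = lambda a, k=2: pt.FitResult(
            pt.ModelSpec("BM1", 1.0, x0=0.0), 0, k, 30, a)
        base = pt.compare([mk(10.0), mk(13.0)], names=["a", "b"])
        ext = pt.compare([mk(10.0), mk(13.0), mk(99.0)],
                         names=["a", "b", "z"])
        assert ext.names[:2] == base.names
        assert ext.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_n_le_k_plus_one_raises(self):
        with pytest.raises(ValueError):
            pt.aicc(0.0, 5, 6)


class TestBmPruning:
    def test_matches_profile_mvn(self):
        for seed in range(5):
            t = pt.yule_tree(15, seed=seed)
            rng = np.random.default_rng(seed)
            x = rng.normal(size=15)
            rates = rng.uniform(0.2, 3.0, size=t.n_nodes)
            ll, x0 = bm_pruning_loglik(t, x, t.edge_length * rates)
            # reference: MVN with per-edge variances, x0 at GLS mean
            mu_, V = _mvn_from_edge_vars(t, t.edge_length * rates)
            one = np.ones(15)
            Vi = np.linalg.inv(V)
            x0_gls = (one @ Vi @ x) / (one @ Vi @ one)
            ll_ref = mvn_logpdf(x, np.full(15, x0_gls), V)
            assert ll == pytest.approx(ll_ref, rel=1e-10, abs=1e-9)
            assert x0 == pytest.approx(x0_gls, abs=1e-9)


def _mvn_from_edge_vars(tree, edge_var):
    tips = tree.tip_indices
    n = len(tips)
    # accumulate shared-edge variances via ancestor chains
    V = np.zeros((n, n))
    anc = []
    for tip in tips:
        chain = {}
        a = int(tip)
        while a != 0:
            chain[a] = edge_var[a]
            a = int(tree.parent[a])
        anc.append(chain)
    for i in range(n):
        for j in range(n):
            shared = set(anc[i]) & set(anc[j])
            V[i, j] = sum(edge_var[e] for e in shared)
    return np.zeros(n), V


class TestBlombergK:
    def test_bm_expectation_near_one(self, yule50):
        paint = pt.RegimeMap.single(yule50)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        ks = []
        for rep in range(300):
            rng = np.random.default_rng([rep, 55])
            real = pt.simulate_realization(yule50, paint, spec, 0.0, rng)
            data = pt.TraitData({yule50.labels[i]: float(real.nodes[i])
                                 for i in yule50.tip_indices})
            ks.append(pt.blomberg_k(yule50, data))
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_white_noise_low_k(self, yule50):
        ks = []
        for rep in range(100):
            rng = np.random.default_rng([rep, 56])
            data = pt.TraitData(dict(zip(yule50.tip_labels,
                                         rng.normal(size=50))))
            ks.append(pt.blomberg_k(yule50, data))
        assert np.mean(ks) < 0.5

    def test_invariant_under_tip_permutation_on_star(self):
        t = pt.read_newick("(A:1,B:1,C:1,D:1);")
        v = [0.1, 0.9, -0.4, 0.3]
        k1 = pt.blomberg_k(t, pt.TraitData(dict(zip("ABCD", v))))
        k2 = pt.blomberg_k(t, pt.TraitData(dict(zip("ABCD",
                                                    v[::-1]))))
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_constant_trait_raises(self, yule50):
        with pytest.raises(ValueError, match="constant"):
            pt.blomberg_k(yule50, pt.TraitData(
                {l: 1.0 for l in yule50.tip_labels}))
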