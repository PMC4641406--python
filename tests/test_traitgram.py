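import math

import numpy as np
import pytest

import phylotraits as pt
from phylotraits.traitgram import BridgeSegment, lines_to_tsv


class TestOuBridge:
    def test_endpoint_exactness(self):
        for alpha in (0.0, 1e-6, 0.5, 3.0, 50.0, 500.0):
            seg = BridgeSegment(0.2, 1.7, x_i=-0.8, x_j=2.1, theta=5.0,
                                alpha=alpha)
            assert pt.ou_bridge(seg, 0.2) == pytest.approx(-0.8, abs=1e-9)
            assert pt.ou_bridge(seg, 1.7) == pytest.approx(2.1, abs=1e-9)

    def test_fixed_point_at_theta(self):
        seg = BridgeSegment(0.0, 2.0, x_i=1.5, x_j=1.5, theta=1.5,
                            alpha=2.0)
        for t in np.linspace(0, 2, 17):
            assert pt.ou_bridge(seg, t) == pytest.approx(1.5, abs=1e-12)

    def test_worked_sinh_ratio_value(self):
        seg = BridgeSegment(0.0, 1.0, x_i=0.0, x_j=1.0, theta=0.0,
                            alpha=1.0)
        expect = math.sinh(0.5) / math.sinh(1.0)
        assert pt.ou_bridge(seg, 0.5) == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(0.44340, abs=1e-5)

    def test_alpha_to_zero_linear_limit(self):
        seg_lin = BridgeSegment(0.0, 1.0, x_i=0.3, x_j=-1.2, alpha=0.0)
        seg_ou = BridgeSegment(0.0, 1.0, x_i=0.3, x_j=-1.2, theta=10.0,
                               alpha=1e-8)
        grid = np.linspace(0, 1, 1000)
        lin = pt.linear_bridge(seg_lin, grid)
        ou = pt.ou_bridge(seg_ou, grid)
        assert np.max(np.abs(lin - ou)) < 1e-6

    def test_large_alpha_no_overflow(self):
        seg = BridgeSegment(0.0, 10.0, x_i=0.0, x_j=1.0, theta=0.5,
                            alpha=200.0)
        v = pt.ou_bridge(seg, 5.0)
        assert np.isfinite(v)
        assert v == pytest.approx(0.5, abs=1e-6)  # pinned to optimum inside

    def test_printed_variant_breaks_right_boundary(self):
        # the as-printed equation anchors both terms at x(t_i) and thus
        # fails to return x(t_j) at the right endpoint
        seg = BridgeSegment(0.0, 1.0, x_i=0.0, x_j=1.0, theta=0.0,
                            alpha=1.0)
        assert pt.ou_bridge(seg, 1.0, as_printed=True) != pytest.approx(
            1.0, abs=1e-3)
        assert pt.ou_bridge(seg, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_outside_segment_raises(self):
        seg = BridgeSegment(0.0, 1.0, x_i=0.0, x_j=1.0, alpha=1.0)
        with pytest.raises(ValueError):
            pt.ou_bridge(seg, 1.5)
        with pytest.raises(ValueError):
            pt.linear_bridge(seg, -0.5)


class TestLinearBridge:
    def test_midpoint(self):
        seg = BridgeSegment(0.0, 1.0, x_i=0.0, x_j=1.0)
        assert pt.linear_bridge(seg, 0.5) == 0.5

    def test_affine_shift_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            xi, xj, c = rng.normal(size=3)
            s1 = BridgeSegment(0.0, 2.0, x_i=xi, x_j=xj)
            s2 = BridgeSegment(0.0, 2.0, x_i=xi + c, x_j=xj + c)
            t = rng.uniform(0, 2)
            assert pt.linear_bridge(s2, t) == pytest.approx(
                pt.linear_bridge(s1, t) + c, abs=1e-12)


class TestInterpolateLineages:
    def _setup(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("OU1", 1.0, alpha=2.0, theta=0.4)
        real = pt.simulate_realization(five_tip, paint, spec, 0.4,
                                       np.random.default_rng(5))
        return paint, spec, real

    def test_node_heights_recover_node_values(self, five_tip):
        paint, spec, real = self._setup(five_tip)
        h = five_tip.height
        vals = pt.interpolate_lineages(five_tip, paint, spec, real,
                                       np.unique(h))
        flat = np.concatenate(vals)
        for v in real.nodes:
            assert np.any(np.abs(flat - v) < 1e-9)

    def test_lineage_count_matches_tree_geometry(self, five_tip):
        paint, spec, real = self._setup(five_tip)
        h = five_tip.height
        grid = np.array([0.0, 0.15, 0.45, 0.65, 0.9, 1.0])
        vals = pt.interpolate_lineages(five_tip, paint, spec, real, grid)
        tol = 1e-9
        for t, v in zip(grid, vals):
            # closed-left: edge spans t if h(parent) <= t < h(child);
            # tips also contribute exactly at their height, root at 0
            expect = sum(1 for u in range(1, five_tip.n_nodes)
                         if h[five_tip.parent[u]] - tol <= t
                         and (t < h[u] - tol
                              or (not five_tip.children[u]
                                  and abs(t - h[u]) <= tol)))
            expect += 1 if abs(t) <= tol else 0
            assert len(v) == expect

    def test_constant_realization_bows_toward_theta(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("OU1", 1.0, alpha=5.0, theta=2.0)
        real = {i: 0.0 for i in range(five_tip.n_nodes)}
        grid = np.array([0.15])   # interior of the root edges
        vals = pt.interpolate_lineages(five_tip, paint, spec, real, grid)
        assert np.all(vals[0] > 0)   # pulled toward theta = 2 from 0

    def test_constant_realization_stays_constant_under_bm(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.7)
        real = {i: 0.7 for i in range(five_tip.n_nodes)}
        vals = pt.interpolate_lineages(five_tip, paint, spec, real,
                                       np.linspace(0, 1, 11))
        for v in vals:
            assert np.allclose(v, 0.7, atol=1e-12)


class TestEnvelope:
    def test_constant_ensemble_degenerate_band(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 0.0, x0=1.3)
        ens = pt.simulate_ensemble(five_tip, paint, spec, 1.3, 0.0,
                                   n_real=20, seed=0)
        env = pt.envelope(ens)
        assert np.allclose(env.lower, 1.3) and np.allclose(env.upper, 1.3)

    def test_root_band_equals_root_value_percentiles(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        ens = pt.simulate_ensemble(five_tip, paint, spec, 0.0, 2.0,
                                   n_real=400, seed=1)
        env = pt.envelope(ens)
        roots = np.array([r.nodes[0] for r in ens.realizations])
        assert env.lower[0] == pytest.approx(
            np.percentile(roots, 2.5, method="inverted_cdf"), abs=1e-9)
        assert env.upper[0] == pytest.approx(
            np.percentile(roots, 97.5, method="inverted_cdf"), abs=1e-9)

    def test_bm_band_width_nondecreasing(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        ens = pt.simulate_ensemble(five_tip, paint, spec, 0.0, 0.0,
                                   n_real=1000, seed=2)
        env = pt.envelope(ens, grid=np.linspace(0, 1, 40))
        width = env.upper - env.lower
        # allow tiny Monte Carlo wiggle
        assert np.all(np.diff(width) > -0.05 * width.max())

    def test_invariant_to_order_and_duplication(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        ens = pt.simulate_ensemble(five_tip, paint, spec, 0.0, 0.0,
                                   n_real=50, seed=3)
        grid = np.linspace(0, 1, 20)
        e1 = pt.envelope(ens, grid=grid)
        ens.realizations = ens.realizations[::-1] + ens.realizations[::-1]
        e2 = pt.envelope(ens, grid=grid)
        assert np.allclose(e1.lower, e2.lower)
        assert np.allclose(e1.upper, e2.upper)

    def test_strong_ou_tip_band_near_stationary(self):
        t = pt.yule_tree(20, seed=20, scale_height=5.0)
        paint = pt.RegimeMap.single(t)
        s2, a, th = 1.0, 4.0, 0.0
        spec = pt.ModelSpec("OU1", s2, alpha=a, theta=th)
        ens = pt.simulate_ensemble(t, paint, spec, th, 0.0,
                                   n_real=500, seed=21)
        env = pt.envelope(ens, grid=np.array([5.0]))
        band = math.sqrt(s2 / (2 * a))
        # extremes over ~20 tips: between ~1 and ~4 stationary SDs
        assert th - 4.5 * band < env.lower[0] < th - 0.8 * band
        assert th + 0.8 * band < env.upper[0] < th + 4.5 * band


class TestTraitgramLines:
    def test_bm_polylines_straight(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        real = pt.simulate_realization(five_tip, paint, spec, 0.0,
                                       np.random.default_rng(7))
        for ln in pt.traitgram_lines(five_tip, paint, spec, real, 10):
            t, v = ln["times"], ln["values"]
            chord = v[0] + (t - t[0]) * (v[-1] - v[0]) / (t[-1] - t[0])
            assert np.allclose(v, chord, atol=1e-12)

    def test_endpoints_equal_node_values(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("OU1", 1.0, alpha=3.0, theta=1.0)
        real = pt.simulate_realization(five_tip, paint, spec, 1.0,
                                       np.random.default_rng(8))
        for ln in pt.traitgram_lines(five_tip, paint, spec, real, 12):
            u = ln["child"]
            assert ln["values"][0] == pytest.approx(
                real.nodes[five_tip.parent[u]], abs=1e-12)
            assert ln["values"][-1] == pytest.approx(real.nodes[u],
                                                     abs=1e-12)

    def test_strong_ou_bows_toward_theta(self):
        t = pt.read_newick("(A:1,B:1);")
        paint = pt.RegimeMap.single(t)
        spec = pt.ModelSpec("OU1", 1.0, alpha=8.0, theta=0.0)
        real = {0: 3.0, 1: 3.0, 2: 3.0}    # far above the optimum
        lines = pt.traitgram_lines(t, paint, spec, real, 30)
        for ln in lines:
            interior = ln["values"][1:-1]
            assert np.all(interior < 3.0)   # deviation toward theta
            assert np.max(3.0 - interior) > 0.5

    def test_tsv_rendering(self, five_tip):
        paint = pt.RegimeMap.single(five_tip)
        spec = pt.ModelSpec("BM1", 1.0, x0=0.0)
        real = pt.simulate_realization(five_tip, paint, spec, 0.0,
                                       np.random.default_rng(9))
        tsv = lines_to_tsv(pt.traitgram_lines(five_tip, paint, spec,
                                              real, 5))
        assert tsv.startswith("edge_child\ttime\tvalue\tregime")
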