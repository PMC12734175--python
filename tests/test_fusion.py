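"""GSAF gate, fusion strategies, and their brute-force oracles."""

import numpy as np
import pytest

from leafgate.branches import BranchConfig, FeatureMap
from leafgate.fusion import (
    AttentionFusion,
    CommonEmbedding,
    GateNetwork,
    HMCTAFModel,
    attention_fusion,
    compute_gate,
    count_gate_parameters,
    fuse_gsaf,
    gate_entropy,
    global_average_pool,
    project_to_common,
    static_fusion,
)
from leafgate.nn import Tensor


def random_gatenet(C=8, h=4, tau=1.0, seed=0):
    net = GateNetwork(C, h, np.random.default_rng(seed), tau=tau)
    # the output layer is zero-initialised (uniform gate at start);
    # randomize it so oracle checks exercise a nontrivial gate
    net.fc2.weight.data = np.random.default_rng(seed + 1).standard_normal(
        net.fc2.weight.data.shape).astype(np.float32)
    return net


class TestGlobalAveragePool:
    def test_map_of_ones_pools_to_ones(self):
        fm = FeatureMap(Tensor(np.ones((2, 3, 5, 7))), 4)
        np.testing.assert_array_equal(global_average_pool(fm).data,
                                      np.ones((2, 3)))

    def test_identity_on_vectors_and_1x1_maps(self):
        v = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(global_average_pool(Tensor(v)).data, v)
        m = v.reshape(2, 3, 1, 1)
        np.testing.assert_array_equal(global_average_pool(Tensor(m)).data, v)

    def test_2x2_map_means(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        np.testing.assert_allclose(global_average_pool(Tensor(m)).data,
                                   [[2.5]])

    def test_empty_spatial_extent_raises(self):
        with pytest.raises(ValueError, match="empty"):
            global_average_pool(Tensor(np.zeros((1, 2, 0, 3))))


class TestGate:
    def test_equal_logit_gate_is_uniform(self):
        net = random_gatenet()
        # force zero logits via zero second-layer weights and bias
        net.fc2.weight.data *= 0
        net.fc2.bias.data *= 0
        z = Tensor(np.random.default_rng(0).standard_normal((4, 8)))
        gw = net(z, z, z)
        np.testing.assert_allclose(gw.gate_array, 1 / 3, atol=1e-7)

    def test_softmax_value_oracle(self):
        """softmax((1,0,0)) = (e/(e+2), 1/(e+2), 1/(e+2))."""
        e = np.exp(1.0)
        expect = np.array([e, 1, 1]) / (e + 2)
        np.testing.assert_allclose(expect, [0.57612, 0.21194, 0.21194],
                                   atol=5e-6)
        s = Tensor(np.array([[1.0, 0.0, 0.0]]))
        np.testing.assert_allclose(s.softmax(axis=-1).data[0], expect,
                                   rtol=1e-10)

    def test_gate_on_simplex_for_many_random_batches(self):
        net = random_gatenet(C=6, h=5)
        rng = np.random.default_rng(1)
        z = Tensor(rng.standard_normal((1000, 6)) * 3)
        gw = net(z, z, z)
        g = gw.gate_array
        assert np.all(g >= 0)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-6)

    def test_descriptor_order_in_u_is_detail_global_transformer(self):
        net = random_gatenet(C=2)
        zd = Tensor(np.array([[1.0, 1.0]]))
        zg = Tensor(np.array([[2.0, 2.0]]))
        zt = Tensor(np.array([[3.0, 3.0]]))
        gw = net(zd, zg, zt)
        np.testing.assert_array_equal(gw.u.data, [[1, 1, 2, 2, 3, 3]])

    def test_temperature_limits(self):
        """tau -> 0 sharpens toward one-hot; tau -> inf flattens to uniform."""
        net = random_gatenet()
        z = Tensor(np.random.default_rng(2).standard_normal((8, 8)))
        sharp = net(z, z, z, tau=1e-4).gate_array
        flat = net(z, z, z, tau=1e4).gate_array
        assert sharp.max(axis=1).min() > 0.999
        np.testing.assert_allclose(flat, 1 / 3, atol=1e-3)

    def test_max_gate_weight_nondecreasing_as_tau_decreases(self):
        net = random_gatenet()
        z = Tensor(np.random.default_rng(3).standard_normal((16, 8)))
        taus = [10.0, 1.0, 0.1, 0.01]
        maxima = [net(z, z, z, tau=t).gate_array.max(axis=1) for t in taus]
        for lo, hi in zip(maxima[:-1], maxima[1:]):
            assert np.all(hi >= lo - 1e-7)

    def test_gate_matches_brute_force_mlp_oracle(self):
        net = random_gatenet(C=3, h=4, seed=5)
        rng = np.random.default_rng(6)
        from scipy.special import erf

        def gelu(x):
            return 0.5 * x * (1 + erf(x / np.sqrt(2)))

        for _ in range(100):
            zd, zg, zt = rng.standard_normal((3, 1, 3))
            u = np.concatenate([zd, zg, zt], axis=1)
            hidden = gelu(u @ net.fc1.weight.data.T + net.fc1.bias.data)
            s = hidden @ net.fc2.weight.data.T + net.fc2.bias.data
            e = np.exp(s - s.max())
            expect = e / e.sum()
            got = net(Tensor(zd), Tensor(zg), Tensor(zt)).gate_array
            np.testing.assert_allclose(got, expect, rtol=1e-5, atol=1e-7)

    def test_nonfinite_descriptors_rejected(self):
        net = random_gatenet()
        bad = Tensor(np.full((1, 8), np.nan))
        with pytest.raises(ValueError, match="non-finite"):
            net(bad, bad, bad)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            random_gatenet(tau=0.0)


class TestGateEntropy:
    def test_uniform_is_ln3(self):
        np.testing.assert_allclose(gate_entropy([1 / 3, 1 / 3, 1 / 3]),
                                   np.log(3), atol=1e-10)

    def test_one_hot_is_zero(self):
        assert gate_entropy([1.0, 0.0, 0.0]) == 0.0

    def test_two_point_uniform_is_ln2(self):
        np.testing.assert_allclose(gate_entropy([0.5, 0.5, 0.0]),
                                   np.log(2), atol=1e-10)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            gate_entropy([-0.1, 0.6, 0.5])

    def test_matches_brute_force_on_random_simplex_points(self):
        rng = np.random.default_rng(0)
        g = rng.dirichlet(np.ones(3), size=200)
        brute = np.array([-sum(p * np.log(p) for p in row if p > 0)
                          for row in g])
        np.testing.assert_allclose(gate_entropy(g), brute, rtol=1e-6)
        np.testing.assert_allclose(gate_entropy(Tensor(g)).data, brute,
                                   rtol=1e-6)


class TestFuseGSAF:
    def _emb(self, arrays):
        return CommonEmbedding(*(Tensor(np.atleast_2d(a)) for a in arrays))

    def _gate(self, g):
        g = Tensor(np.atleast_2d(np.asarray(g, dtype=float)))
        return type("G", (), {"g": g})()

    def test_one_hot_gate_passes_through_detail(self):
        emb = self._emb([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = fuse_gsaf(self._gate([1, 0, 0]), emb)
        np.testing.assert_array_equal(out.phi.data, [[1, 2]])

    def test_uniform_gate_is_arithmetic_mean(self):
        emb = self._emb([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = fuse_gsaf(self._gate([1 / 3, 1 / 3, 1 / 3]), emb)
        np.testing.assert_allclose(out.phi.data, [[2 / 3, 2 / 3]], rtol=1e-7)

    def test_matches_weighted_sum_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            phis = rng.standard_normal((3, 4, 6))
            g = rng.dirichlet(np.ones(3), size=4)
            emb = CommonEmbedding(*(Tensor(p) for p in phis))
            gate = type("G", (), {"g": Tensor(g)})()
            expect = np.einsum("bi,ibc->bc", g, phis)
            np.testing.assert_allclose(fuse_gsaf(gate, emb).phi.data, expect,
                                       rtol=1e-6, atol=1e-9)

    def test_convex_hull_bound_on_fused_embedding(self):
        rng = np.random.default_rng(2)
        net = random_gatenet(C=5)
        for _ in range(50):
            phis = rng.standard_normal((3, 8, 5))
            emb = CommonEmbedding(*(Tensor(p) for p in phis))
            gw = net(emb.phi_d, emb.phi_g, emb.phi_t)
            phi = fuse_gsaf(gw, emb).phi.data
            bound = np.abs(phis).max(axis=0).max(axis=-1)  # per-sample inf-norm
            assert np.all(np.abs(phi).max(axis=-1) <= bound + 1e-6)

    def test_width_mismatch_raises(self):
        emb = CommonEmbedding(Tensor(np.zeros((1, 3))),
                              Tensor(np.zeros((1, 4))),
                              Tensor(np.zeros((1, 3))))
        with pytest.raises(ValueError, match="width"):
            fuse_gsaf(self._gate([1, 0, 0]), emb)


class TestProjection:
    def test_constant_map_pools_to_projected_value(self):
        C = 3
        detail = FeatureMap(Tensor(np.full((1, 2, 4, 4), 2.0)), 4)
        glob = FeatureMap(Tensor(np.full((1, 2, 2, 2), 1.0)), 32)
        cls = Tensor(np.zeros((1, 5)))
        emb = project_to_common(detail, glob, cls, C, seed=0)
        assert emb.phi_d.shape == (1, C)
        assert emb.phi_g.shape == (1, C)
        assert emb.phi_t.shape == (1, C)

    def test_known_1x1_kernel_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        from leafgate.nn import Conv2d
        conv = Conv2d(2, 3, 1, rng)
        m = rng.standard_normal((1, 2, 2, 2)).astype(np.float32)
        pooled = global_average_pool(conv(Tensor(m))).data
        # oracle: project per pixel then average
        w = conv.weight.data[:, :, 0, 0]
        expect = (np.einsum("oc,bchw->bohw", w, m).mean(axis=(2, 3))
                  + conv.bias.data)
        np.testing.assert_allclose(pooled, expect, rtol=1e-5, atol=1e-6)

    def test_nonpositive_width_rejected(self):
        detail = FeatureMap(Tensor(np.zeros((1, 2, 4, 4))), 4)
        glob = FeatureMap(Tensor(np.zeros((1, 2, 2, 2))), 32)
        with pytest.raises(ValueError, match="positive"):
            project_to_common(detail, glob, Tensor(np.zeros((1, 5))), 0)


class TestAttentionFusion:
    def test_equal_scores_give_mean_of_projections(self):
        rng = np.random.default_rng(0)
        mod = AttentionFusion((4, 4, 4), 6, rng)
        # zero the scorer's last layer -> equal scores
        mod.scorer.steps[-1].weight.data *= 0
        mod.scorer.steps[-1].bias.data *= 0
        vs = [Tensor(rng.standard_normal((2, 4))) for _ in range(3)]
        fused, alpha = mod(*vs)
        np.testing.assert_allclose(alpha.data, 1 / 3, atol=1e-7)
        projs = [p(v).data for p, v in zip(
            (mod.proj_d, mod.proj_g, mod.proj_t), vs)]
        np.testing.assert_allclose(fused.data, np.mean(projs, axis=0),
                                   rtol=1e-5, atol=1e-6)

    def test_dominant_score_saturates_to_one_branch(self):
        rng = np.random.default_rng(1)
        mod = AttentionFusion((4, 4, 4), 6, rng)
        vs = [Tensor(rng.standard_normal((1, 4))) for _ in range(3)]
        f = np.stack([p(v).data for p, v in zip(
            (mod.proj_d, mod.proj_g, mod.proj_t), vs)], axis=1)
        # emulate a huge score gap by calling softmax on manual scores
        alpha = Tensor(np.array([[50.0, 0.0, 0.0]])).softmax(axis=-1).data
        fused = (alpha[..., None] * f).sum(axis=1)
        np.testing.assert_allclose(fused, f[:, 0], rtol=1e-6, atol=1e-6)

    def test_matches_hand_rolled_mlp_softmax_weighted_sum(self):
        rng = np.random.default_rng(2)
        from scipy.special import erf
        mod = AttentionFusion((4, 4, 4), 4, rng, score_hidden=3)

        def gelu(x):
            return 0.5 * x * (1 + erf(x / np.sqrt(2)))

        for _ in range(100):
            vs = rng.standard_normal((3, 2, 4))
            f = np.stack([
                vs[0] @ mod.proj_d.weight.data.T + mod.proj_d.bias.data,
                vs[1] @ mod.proj_g.weight.data.T + mod.proj_g.bias.data,
                vs[2] @ mod.proj_t.weight.data.T + mod.proj_t.bias.data,
            ], axis=1)
            l1, l2 = mod.scorer.steps[0], mod.scorer.steps[2]
            scores = (gelu(f @ l1.weight.data.T + l1.bias.data)
                      @ l2.weight.data.T + l2.bias.data)[..., 0]
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            alpha = e / e.sum(axis=1, keepdims=True)
            expect = np.einsum("bi,bic->bc", alpha, f)
            got = attention_fusion(*(Tensor(v) for v in vs), module=mod)
            np.testing.assert_allclose(got.phi.data, expect, rtol=1e-5,
                                       atol=1e-6)


class TestStaticFusion:
    def test_average_of_identical_vectors_is_identity(self):
        v = np.random.default_rng(0).standard_normal((2, 4))
        out = static_fusion([v, v, v], "average")
        np.testing.assert_allclose(out.phi.data, v, rtol=1e-7)

    def test_concat_width_is_sum_of_native_widths(self):
        out = static_fusion([np.zeros((1, 64)), np.zeros((1, 128)),
                             np.zeros((1, 768))], "concat")
        assert out.phi.shape == (1, 960)

    def test_average_known_vectors(self):
        out = static_fusion([np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]),
                             np.array([[1.0, 1.0]])], "average")
        np.testing.assert_allclose(out.phi.data, [[2 / 3, 2 / 3]], rtol=1e-7)

    def test_average_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal widths"):
            static_fusion([np.zeros((1, 3)), np.zeros((1, 4)),
                           np.zeros((1, 3))], "average")


class TestGateParameterCount:
    @pytest.mark.parametrize("C,h,expect", [
        (256, 12, 9267), (64, 32, 6275), (1, 1, 10)])
    def test_formula_values(self, C, h, expect):
        assert count_gate_parameters(C, h) == expect

    @pytest.mark.parametrize("C,h", [(256, 12), (32, 12), (8, 4)])
    def test_formula_matches_constructed_module(self, C, h):
        net = GateNetwork(C, h, np.random.default_rng(0))
        assert net.n_parameters() == count_gate_parameters(C, h)

    def test_default_configuration_stays_under_10k(self):
        cfg = BranchConfig.full()
        assert count_gate_parameters(cfg.common_dim, cfg.gate_hidden) < 10_000


class TestGradientFlow:
    def test_loss_on_fused_embedding_reaches_gate_and_all_branches(self):
        rng = np.random.default_rng(0)
        C = 5
        net = random_gatenet(C=C)
        phis = [Tensor(rng.standard_normal((3, C)), requires_grad=True)
                for _ in range(3)]
        emb = CommonEmbedding(*phis)
        gw = net(*phis)
        phi = fuse_gsaf(gw, emb).phi
        (phi * phi).sum().backward()
        for p in (net.fc1.weight, net.fc1.bias, net.fc2.weight, net.fc2.bias):
            assert p.grad is not None and np.any(p.grad != 0)
        for t in phis:
            assert t.grad is not None and np.any(t.grad != 0)


class TestModelStrategies:
    @pytest.mark.parametrize("strategy,has_gate", [
        ("gsaf", True), ("static_average", False), ("attention", False),
        ("static_concat", False), ("detail_only", False), ("vit_only", False),
        ("cnns_only", False), ("cross_attention", False),
    ])
    def test_forward_shapes_and_gate_presence(self, strategy, has_gate):
        cfg = BranchConfig.tiny()
        m = HMCTAFModel(cfg, 4, strategy=strategy, seed=0)
        x = Tensor(np.random.default_rng(0).random((2, 3, 64, 64))
                   .astype(np.float32))
        m.eval()
        logits, gates = m(x)
        assert logits.shape == (2, 4)
        assert (gates is not None) == has_gate

    def test_single_branch_strategy_has_no_gate_parameters(self):
        cfg = BranchConfig.tiny()
        m = HMCTAFModel(cfg, 4, strategy="detail_only", seed=0)
        names = [n for n, _ in m.named_parameters()]
        assert not any("gate" in n or "proj" in n for n in names)

    def test_gsaf_exceeds_static_average_by_exact_gate_count(self):
        cfg = BranchConfig.tiny()
        gsaf = HMCTAFModel(cfg, 4, strategy="gsaf", seed=0)
        static = HMCTAFModel(cfg, 4, strategy="static_average", seed=0)
        diff = gsaf.n_parameters() - static.n_parameters()
        assert diff == count_gate_parameters(cfg.common_dim, cfg.gate_hidden)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            HMCTAFModel(BranchConfig.tiny(), 4, strategy="nope")

    def test_compute_gate_functional_wrapper(self):
        net = random_gatenet(C=4)
        z = np.random.default_rng(0).standard_normal(4)
        gw = compute_gate(z, z, z, net)
        np.testing.assert_allclose(gw.gate_array.sum(), 1.0, atol=1e-6)
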