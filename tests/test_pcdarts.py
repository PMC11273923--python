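"""Differentiable search: mixed edges, partial channels, discretization."""

import numpy as np
import pytest

from agenas import nn
from agenas.complexity import count_network
from agenas.pcdarts import (ArchParams, CellGenotype, SearchHyper,
                            SearchNetwork, SearchNetworkConfig, bilevel_search,
                            build_agenet, build_agenet_network, derive_genotype,
                            mixed_edge_forward, node_aggregate,
                            partial_mixed_edge_forward)

TOY_CFG = SearchNetworkConfig(
    num_cells=2, reduction_positions=(2,), init_channels=36, num_nodes=2,
    input_channels=1, num_classes=10, sample_ratio=0.25)


class TestMixedEdge:
    def test_single_operator_passthrough(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 4, 5, 5)))
        out = mixed_edge_forward(x, np.array([3.7]), [nn.Identity()])
        assert np.allclose(out.data, x.data)

    def test_identity_zero_equal_weights(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 4, 5, 5)))
        out = mixed_edge_forward(x, np.zeros(2), [nn.Identity(), nn.Zero()])
        assert np.allclose(out.data, 0.5 * x.data)

    def test_softmax_weights_values(self, rng):
        x = nn.Tensor(np.ones((1, 2, 3, 3)))
        ops = [nn.Zero(), nn.Zero(), nn.Identity()]
        out = mixed_edge_forward(x, np.array([1.0, 2.0, 3.0]), ops)
        # softmax(1,2,3) = (0.0900, 0.2447, 0.6652)
        assert np.allclose(out.data, 0.6652, atol=1e-4)

    def test_shape_mismatch_raises(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 4, 6, 6)))
        ops = [nn.Identity(), nn.AvgPool2d(3, 2)]
        with pytest.raises(ValueError, match="shape"):
            mixed_edge_forward(x, np.zeros(2), ops)


class TestPartialChannels:
    def test_all_ones_mask_reduces_to_full_mixture(self, rng):
        """With S = 1 the partial mixture equals the plain mixture exactly."""
        x = nn.Tensor(rng.normal(size=(2, 6, 5, 5)))
        alpha = rng.normal(size=3)
        ops = [nn.Identity(), nn.Zero(), nn.AvgPool2d(3, 1)]
        full = mixed_edge_forward(x, alpha, ops)
        part = partial_mixed_edge_forward(x, alpha, np.ones(6), ops)
        assert np.array_equal(part.data, full.data)

    def test_all_zeros_mask_is_identity(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 6, 5, 5)))
        out = partial_mixed_edge_forward(x, np.zeros(3), np.zeros(6),
                                         [nn.Identity()] * 3)
        assert np.array_equal(out.data, x.data)

    def test_identity_ops_leave_input_unchanged(self, rng):
        mask = np.zeros(8)
        mask[rng.permutation(8)[:3]] = 1
        x = nn.Tensor(rng.normal(size=(2, 8, 4, 4)))
        out = partial_mixed_edge_forward(x, np.zeros(1), mask, [nn.Identity()])
        assert np.allclose(out.data, x.data)

    def test_bypass_channels_keep_gradient_identity(self, rng):
        """Masked-out channels transmit gradients as a pure identity path."""
        mask = np.array([1, 0, 0, 1])
        x = nn.Tensor(rng.normal(size=(1, 4, 3, 3)), requires_grad=True)
        out = partial_mixed_edge_forward(x, np.zeros(1), mask, [nn.Zero()])
        out.sum().backward()
        bypass = ~mask.astype(bool)
        assert np.allclose(x.grad[:, bypass], 1.0)
        assert np.allclose(x.grad[:, mask.astype(bool)], 0.0)


class TestNodeAggregate:
    def test_single_edge_unscaled(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 3, 2, 2)))
        out = node_aggregate({0: x}, {0: nn.Tensor(np.array(2.3))})
        assert np.allclose(out.data, x.data)

    def test_equal_betas_average(self, rng):
        a = nn.Tensor(rng.normal(size=(1, 3, 2, 2)))
        b = nn.Tensor(rng.normal(size=(1, 3, 2, 2)))
        out = node_aggregate({0: a, 1: b},
                             {0: nn.Tensor(np.array(0.0)),
                              1: nn.Tensor(np.array(0.0))})
        assert np.allclose(out.data, (a.data + b.data) / 2)

    def test_log_beta_weights(self):
        a = nn.Tensor(np.ones((1, 1, 1, 1)))
        b = nn.Tensor(np.full((1, 1, 1, 1), 2.0))
        out = node_aggregate({0: a, 1: b},
                             {0: nn.Tensor(np.log(1.0)),
                              1: nn.Tensor(np.log(3.0))})
        assert np.allclose(out.data, 0.25 * 1 + 0.75 * 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            node_aggregate({}, {})


def _toy_data(rng, n=20):
    return rng.normal(size=(n, 1, 12, 12)), rng.integers(0, 10, n)


class TestBilevelSearch:
    def test_deterministic_given_seed(self, rng):
        xs, ys = _toy_data(rng, 16)
        runs = []
        for _ in range(2):
            arch, _ = bilevel_search((xs[:10], ys[:10]), (xs[10:], ys[10:]),
                                     TOY_CFG, SearchHyper(steps=2, batch_size=4,
                                                          seed=3))
            runs.append({k: v.data.copy() for k, v in arch.alpha.items()})
        assert all(np.array_equal(runs[0][k], runs[1][k]) for k in runs[0])

    def test_alpha_finite_and_normalized_after_steps(self, rng):
        xs, ys = _toy_data(rng, 16)
        arch, log = bilevel_search((xs[:10], ys[:10]), (xs[10:], ys[10:]),
                                   TOY_CFG, SearchHyper(steps=4, batch_size=4,
                                                        seed=0))
        assert len(log) == 4
        for key in arch.alpha:
            sa = arch.softmax_alpha(key)
            assert np.all(np.isfinite(arch.alpha[key].data))
            assert sa.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mask_fraction_matches_sample_ratio(self, rng):
        xs, ys = _toy_data(rng, 8)
        arch, _ = bilevel_search((xs[:5], ys[:5]), (xs[5:], ys[5:]), TOY_CFG,
                                 SearchHyper(steps=1, batch_size=2, seed=0))
        for key, mask in arch.mask.items():
            assert set(np.unique(mask)) <= {0, 1}
            c = len(mask)
            assert abs(mask.sum() - TOY_CFG.sample_ratio * c) <= 1

    def test_empty_split_rejected(self, rng):
        xs, ys = _toy_data(rng, 4)
        with pytest.raises(ValueError):
            bilevel_search((xs, ys), (xs[:0], ys[:0]), TOY_CFG)

    def test_single_step_moves_mass_toward_zero_loss_op(self, rng):
        """Two-operator edge: the op matching the target gains alpha mass."""
        x = nn.Tensor(rng.normal(size=(4, 3, 6, 6)))
        alpha = nn.Parameter(np.zeros(2))
        ops = [nn.Identity(), nn.Zero()]  # target == x: identity is perfect
        opt = nn.Adam([alpha], lr=0.05)
        out = mixed_edge_forward(x, alpha, ops)
        loss = ((out - x) ** 2.0).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        assert alpha.data[0] > alpha.data[1]

    def test_informative_operator_wins_across_seeds(self):
        """With one informative operator (the target is exactly its output),
        alpha ranks it first in at least 8 of 10 seeded runs."""
        wins = 0
        pool = nn.AvgPool2d(3, 1)
        for seed in range(10):
            srng = np.random.default_rng(seed)
            ops = [nn.Identity(), nn.Zero(), pool]
            alpha = nn.Parameter(1e-3 * srng.normal(size=3))
            opt = nn.Adam([alpha], lr=0.1)
            for _ in range(30):
                x = nn.Tensor(srng.normal(size=(8, 2, 8, 8)))
                target = pool(x).detach()
                out = mixed_edge_forward(x, alpha, ops)
                loss = ((out - target) ** 2.0).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
            wins += int(np.argmax(alpha.data) == 2)
        assert wins >= 8


class TestGenotype:
    def _hand_params(self):
        cfg = SearchNetworkConfig(num_cells=1, reduction_positions=(),
                                  init_channels=9, num_nodes=2,
                                  input_channels=1, num_classes=4,
                                  operators=("identity", "avg_pool_3x3", "zero"))
        arch = ArchParams.initialize(2, 3, 0.5, np.random.default_rng(0),
                                     cell_types=("normal",))
        return cfg, arch

    def test_hand_built_table_matches_enumeration(self):
        cfg, arch = self._hand_params()
        # node 2: edge (0,2) prefers avg_pool with beta 2.0;
        #         edge (1,2) prefers identity with beta 0.0
        arch.alpha[("normal", 0, 2)].data = np.array([0.0, 3.0, 0.0])
        arch.beta[("normal", 0, 2)].data = np.array(2.0)
        arch.alpha[("normal", 1, 2)].data = np.array([4.0, 0.0, 0.0])
        arch.beta[("normal", 1, 2)].data = np.array(0.0)
        # node 3: three incoming edges; (2,3) weakest by beta*opweight
        arch.alpha[("normal", 0, 3)].data = np.array([5.0, 0.0, 0.0])
        arch.beta[("normal", 0, 3)].data = np.array(1.0)
        arch.alpha[("normal", 1, 3)].data = np.array([0.0, 5.0, 0.0])
        arch.beta[("normal", 1, 3)].data = np.array(1.0)
        arch.alpha[("normal", 2, 3)].data = np.array([0.0, 0.0, 5.0])
        arch.beta[("normal", 2, 3)].data = np.array(-3.0)
        g = derive_genotype(arch, cfg)
        assert g.normal[0:2] == (("avg_pool_3x3", 0), ("identity", 1))
        # (2,3) has high alpha only on zero, low beta: excluded
        assert g.normal[2:4] == (("identity", 0), ("avg_pool_3x3", 1))

    def test_zero_operator_never_selected(self):
        cfg, arch = self._hand_params()
        for key in arch.alpha:
            arch.alpha[key].data = np.array([0.0, 0.0, 9.0])  # peak on zero
        g = derive_genotype(arch, cfg)
        assert all(op != "zero" for op, _ in g.normal + g.reduce)

    def test_tie_breaks_prefer_lower_source(self):
        cfg, arch = self._hand_params()
        for key in arch.alpha:
            arch.alpha[key].data = np.zeros(3)
            arch.beta[key].data = np.array(0.0)
        g = derive_genotype(arch, cfg)
        assert [src for _, src in g.normal] == [0, 1, 0, 1]

    def test_json_round_trip_and_validation(self):
        g = CellGenotype(normal=(("identity", 0), ("sep_conv_3x3", 1),
                                 ("avg_pool_3x3", 1), ("conv_3x3", 2)),
                         reduce=(("max_pool_3x3", 0), ("identity", 1),
                                 ("sep_conv_5x5", 0), ("identity", 2)),
                         nodes=2)
        assert CellGenotype.from_dict(g.to_dict()) == g
        with pytest.raises(ValueError, match="zero"):
            CellGenotype(normal=(("zero", 0), ("identity", 1),
                                 ("identity", 0), ("identity", 1)),
                         reduce=g.reduce, nodes=2)
        with pytest.raises(ValueError, match="source"):
            CellGenotype(normal=(("identity", 2), ("identity", 1),
                                 ("identity", 0), ("identity", 1)),
                         reduce=g.reduce, nodes=2)


class TestAgeNetBuilder:
    GENO = CellGenotype(
        normal=(("sep_conv_3x3", 0), ("identity", 1),
                ("group_conv_3x3_g9", 1), ("avg_pool_3x3", 2)),
        reduce=(("max_pool_3x3", 0), ("asym_conv_1x7_7x1_g9", 1),
                ("identity", 2), ("sep_conv_5x5", 1)),
        nodes=2)

    def test_cell_mix_five_normal_three_reduction(self):
        spec = build_agenet(self.GENO, init_channels=36)
        assert spec["num_cells"] == 8
        assert spec["reduction_positions"] == [1, 3, 6]

    def test_channel_presets(self):
        small = build_agenet(self.GENO, init_channels=36)
        large = build_agenet(self.GENO, init_channels=54)
        assert small["init_channels"] == 36 and large["init_channels"] == 54
        assert (count_network(large, 384).params
                > count_network(small, 384).params)

    def test_spatial_reduction_after_stem_and_reductions(self):
        """Final grid = input / 2^(2 stem strides + 3 reductions)."""
        spec = build_agenet(self.GENO, init_channels=36)
        conv_scales = [l["out_scale"] for l in spec["layers"]
                       if l["op"] == "conv"]
        assert max(conv_scales) == 2 ** 5

    def test_runtime_matches_counter_params(self, rng):
        spec = build_agenet(self.GENO, init_channels=18, num_cells=2,
                            reduction_positions=(2,), input_channels=1,
                            num_classes=10)
        net = build_agenet_network(spec, rng=rng)
        assert net.num_params() == count_network(spec, 32).params
        out = net(nn.Tensor(rng.normal(size=(2, 1, 16, 16))))
        assert out.data.shape == (2, 10)


class TestSearchNetworkConfig:
    def test_reduction_positions_validated(self):
        with pytest.raises(ValueError):
            SearchNetworkConfig(num_cells=4, reduction_positions=(5,))
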