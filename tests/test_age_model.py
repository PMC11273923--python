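"""Expectation head, smoothing targets, metrics, training loop."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agenas import nn
from agenas.age_model import (AgeDistribution, TrainConfig, clamp_ages,
                              cumulative_score, dex_expected_age,
                              dex_ages_from_logits, evaluate,
                              label_smoothing_target, label_smoothing_targets,
                              load_manifest, mae, per_age_group_mae,
                              predict_with_mirror, train)


class TestExpectation:
    def test_one_hot(self):
        probs = np.zeros(76)
        probs[30] = 1.0
        assert dex_expected_age(AgeDistribution(probs)).age_years == 30.0

    def test_uniform(self):
        assert dex_expected_age(
            AgeDistribution(np.full(76, 1 / 76))).age_years == pytest.approx(37.5)

    def test_two_point(self):
        probs = np.zeros(76)
        probs[10], probs[20] = 0.2, 0.8
        assert dex_expected_age(AgeDistribution(probs)).age_years == pytest.approx(18.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            AgeDistribution(np.full(76, 0.5))
        with pytest.raises(ValueError):
            AgeDistribution(np.array([1.5, -0.5] + [0.0] * 74))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30)
    def test_expectation_always_within_label_range(self, seed):
        gen = np.random.default_rng(seed)
        probs = gen.dirichlet(np.ones(76))
        y = dex_expected_age(AgeDistribution(probs)).age_years
        assert 0.0 <= y <= 75.0

    def test_batch_expectation_matches_single(self, rng):
        logits = rng.normal(size=(5, 76))
        batch = dex_ages_from_logits(logits)
        for i in range(5):
            p = np.exp(logits[i] - logits[i].max())
            single = dex_expected_age(AgeDistribution(p / p.sum())).age_years
            assert batch[i] == pytest.approx(single)


class TestLabelSmoothing:
    def test_eps_zero_is_one_hot(self):
        t = label_smoothing_target(12, eps=0.0)
        assert t.probs[12] == 1.0 and t.probs.sum() == 1.0

    def test_off_bin_mass(self):
        t = label_smoothing_target(40, k=76, eps=0.1)
        off = np.delete(t.probs, 40)
        assert np.allclose(off, 0.1 / 75)
        assert t.probs[40] == pytest.approx(0.9)
        assert t.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_smoothing_target(76)

    def test_batch_targets_clamp_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="agenas.age_model"):
            t = label_smoothing_targets(np.array([5, 93]), eps=0.0)
        assert t[1].argmax() == 75
        assert "clamping" in caplog.text

    def test_clamp_passthrough_in_range(self):
        ages = np.array([0, 40, 75])
        assert np.array_equal(clamp_ages(ages), ages)


class _OrientationProbe(nn.Module):
    """Test double: peaked logits at age 20 normally, 24 when mirrored."""

    def __init__(self, reference):
        self.reference = reference

    def forward(self, x):
        logits = np.zeros((x.data.shape[0], 76))
        peak = 20 if np.allclose(x.data, self.reference) else 24
        logits[:, peak] = 50.0
        return nn.Tensor(logits)


class TestMirrorInference:
    def test_averaging_contract(self, rng):
        img = rng.normal(size=(1, 8, 8))
        pred = predict_with_mirror(_OrientationProbe(img[None]), img)
        assert pred.age_years == pytest.approx(22.0)

    def test_symmetric_input_equals_plain_prediction(self, tiny_plan, rng):
        from agenas.spos import build_path_network, sample_path
        net = build_path_network(tiny_plan, sample_path(rng, 4), rng=rng)
        net.eval()
        half = rng.random(size=(1, 16, 8))
        img = np.concatenate([half, half[..., ::-1]], axis=-1)
        plain = dex_ages_from_logits(net(nn.Tensor(img[None])).data)[0]
        mirrored = predict_with_mirror(net, img).age_years
        assert mirrored == pytest.approx(plain, abs=1e-9)


class TestMetrics:
    def test_mae_basics(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert mae([21, 19], [20, 20]) == 1.0
        with pytest.raises(ValueError):
            mae([1, 2], [1])

    def test_mae_matches_independent_recomputation(self, rng):
        pred = rng.uniform(0, 75, 1000)
        true = rng.integers(0, 76, 1000)
        oracle = sum(abs(float(p) - float(t)) for p, t in zip(pred, true)) / 1000
        assert mae(pred, true) == pytest.approx(oracle)

    def test_cumulative_score(self):
        assert cumulative_score([5, 6], [5, 6], 0) == 100.0
        assert cumulative_score([0.5, 1.5, 2.5], [0, 0, 0], 2) == pytest.approx(
            100 * 2 / 3)

    def test_cs_monotone_and_mae_consistency(self, rng):
        pred = rng.uniform(0, 75, 200)
        true = rng.uniform(0, 75, 200)
        cs = [cumulative_score(pred, true, j) for j in (0, 1, 2, 5, 80)]
        assert all(a <= b for a, b in zip(cs, cs[1:]))
        assert cs[-1] == 100.0
        assert mae(pred, true) <= 80

    def test_per_bin_single_pair(self):
        assert per_age_group_mae([6.0], [5.0]) == {"0-10": 1.0}

    def test_per_bin_weighted_mean_equals_global(self, rng):
        pred = rng.uniform(0, 75, 300)
        true = rng.integers(0, 76, 300)
        bins = per_age_group_mae(pred, true)
        weights = {k: np.sum((true >= int(k.split("-")[0]))
                             & (true < int(k.split("-")[1]))) for k in bins}
        weighted = sum(bins[k] * weights[k] for k in bins) / sum(weights.values())
        assert weighted == pytest.approx(mae(pred, true))

    def test_empty_bins_absent(self):
        assert "10-20" not in per_age_group_mae([3.0, 55.0], [2, 57])


class TestTraining:
    def test_loss_decreases_on_toy_data(self, small_synth):
        from agenas.spos import SupernetPlan, PathCode, build_path_network
        images, ages = small_synth
        plan = SupernetPlan(stem_cout=8, couts=(8, 16), strides=(2, 2),
                            expands=(1.0, 2.0), head_cout=32,
                            input_channels=1)
        net = build_path_network(plan, PathCode((0, 2)),
                                 rng=np.random.default_rng(0))
        net, log = train(net, (images, ages),
                         TrainConfig(epochs=3, batch_size=16, lr=3e-3,
                                     augment=False, seed=5))
        assert log[-1]["loss"] < log[0]["loss"]

    def test_bitwise_reproducible_without_augmentation(self, small_synth):
        from agenas.spos import SupernetPlan, PathCode, build_path_network
        images, ages = small_synth
        plan = SupernetPlan(stem_cout=8, couts=(8,), strides=(2,),
                            expands=(1.0,), head_cout=16, input_channels=1)
        curves = []
        for _ in range(2):
            net = build_path_network(plan, PathCode((1,)),
                                     rng=np.random.default_rng(3))
            _, log = train(net, (images[:16], ages[:16]),
                           TrainConfig(epochs=2, batch_size=8, lr=1e-3,
                                       augment=False, seed=7))
            curves.append([row["loss"] for row in log])
        assert curves[0] == curves[1]

    def test_augmentation_is_seeded(self, small_synth):
        from agenas.spos import SupernetPlan, PathCode, build_path_network
        images, ages = small_synth
        plan = SupernetPlan(stem_cout=8, couts=(8,), strides=(2,),
                            expands=(1.0,), head_cout=16, input_channels=1)
        curves = []
        for _ in range(2):
            net = build_path_network(plan, PathCode((1,)),
                                     rng=np.random.default_rng(3))
            _, log = train(net, (images[:16], ages[:16]),
                           TrainConfig(epochs=1, batch_size=8, lr=1e-3,
                                       augment=True, seed=11))
            curves.append([row["loss"] for row in log])
        assert curves[0] == curves[1]

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            train(nn.Identity(), (np.zeros((0, 1, 8, 8)), np.zeros(0)),
                  TrainConfig(epochs=1))


class TestManifestIO:
    def test_round_trip_and_bad_rows(self, tmp_path, caplog):
        from agenas.synth_opg import SynthConfig, generate_dataset
        manifest = generate_dataset(SynthConfig(n=6, seed=1), tmp_path)
        images, ages = load_manifest(manifest)
        assert images.shape == (6, 1, 64, 64)
        assert len(ages) == 6
        # append an unreadable row: skipped with a warning
        with open(manifest, "a") as fh:
            fh.write("missing.png,30\n")
        with caplog.at_level(logging.WARNING, logger="agenas.age_model"):
            images2, ages2 = load_manifest(manifest)
        assert len(ages2) == 6
        assert "skipping" in caplog.text

    def test_evaluate_report_structure(self, small_synth):
        from agenas.spos import SupernetPlan, PathCode, build_path_network
        images, ages = small_synth
        plan = SupernetPlan(stem_cout=8, couts=(8,), strides=(2,),
                            expands=(1.0,), head_cout=16, input_channels=1)
        net = build_path_network(plan, PathCode((0,)),
                                 rng=np.random.default_rng(0))
        rep = evaluate(net, (images, ages))
        assert rep.n == len(ages)
        cs = [rep.cs_curve[j] for j in sorted(rep.cs_curve)]
        assert all(a <= b for a, b in zip(cs, cs[1:]))
        assert set(rep.to_dict()) == {"mae", "cs_curve", "per_bin_mae", "n"}
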