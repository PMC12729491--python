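"""Model assembly: determinism, shape/range contracts, ablation factory, checkpoints."""

import numpy as np
import pytest

import waveseg.nn as nn
from waveseg.errors import ConfigurationError, ValidationError
from waveseg.losses_metrics import hybrid_loss
from waveseg.network import (ABLATION_NAMES, ModelConfig,
                             build_model, count_parameters, load_checkpoint,
                             make_ablation_suite, save_checkpoint)


def reduced_cfg(**overrides) -> ModelConfig:
    base = dict(num_stages=4, base_width=8, image_size=64, seed=3,
                wtconv_stages=frozenset({3, 4}), lrfa_stages=frozenset({4}))
    base.update(overrides)
    return ModelConfig(**base)


class TestConfigValidation:
    def test_stage_indices_must_be_in_range(self):
        with pytest.raises(ConfigurationError, match="wtconv_stages"):
            build_model(reduced_cfg(wtconv_stages=frozenset({5})))

    def test_image_size_divisibility(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            build_model(reduced_cfg(image_size=60))

    def test_lrfa_token_budget_enforced_at_config_time(self):
        with pytest.raises(ConfigurationError, match="tokens"):
            build_model(reduced_cfg(lrfa_stages=frozenset({1})))
        # 256x256 with the bottleneck at 16x16 = 256 tokens is fine
        build_model(ModelConfig(image_size=256, base_width=8, seed=0))


class TestBuildAndForward:
    def test_seeded_build_is_reproducible(self):
        a = build_model(reduced_cfg(seed=11))
        b = build_model(reduced_cfg(seed=11))
        assert count_parameters(a) == count_parameters(b)
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_different_seeds_differ(self):
        a = build_model(reduced_cfg(seed=1))
        b = build_model(reduced_cfg(seed=2))
        assert any(
            not np.array_equal(pa.data, pb.data)
            for pa, pb in zip(a.parameters(), b.parameters())
        )

    def test_output_shape_and_open_unit_range(self, rng):
        model = build_model(reduced_cfg())
        out = model(rng.standard_normal((2, 3, 64, 64)) * 10.0)
        assert out.shape == (2, 1, 64, 64)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_forward_deterministic_in_double_precision(self, rng):
        model = build_model(reduced_cfg())
        x = rng.standard_normal((1, 3, 64, 64))
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_transpose_upsampling_mode(self, rng):
        model = build_model(reduced_cfg(upsample_mode="transpose"))
        out = model(rng.standard_normal((1, 3, 64, 64)))
        assert out.shape == (1, 1, 64, 64)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_no_cross_batch_leakage(self, rng):
        model = build_model(reduced_cfg())
        img = rng.standard_normal((1, 3, 64, 64))
        doubled = model(np.concatenate([img, img])).data
        np.testing.assert_allclose(doubled[0], doubled[1], atol=1e-12)

    def test_indivisible_input_names_required_divisor(self, rng):
        model = build_model(reduced_cfg())
        with pytest.raises(ValidationError, match="divisible by 8"):
            model(rng.standard_normal((1, 3, 60, 60)))

    def test_every_parameter_receives_gradient(self, rng):
        model = build_model(reduced_cfg(num_stages=3, base_width=8, image_size=32,
                                        wtconv_stages=frozenset({3}),
                                        lrfa_stages=frozenset({3})))
        x = rng.standard_normal((2, 3, 32, 32))
        target = (rng.random((2, 1, 32, 32)) > 0.5).astype(float)
        loss = hybrid_loss(model(x), target)
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name


class TestParameterCounting:
    def test_single_conv_example(self):
        conv = nn.Conv2d(3, 1, 1, np.random.default_rng(0))
        assert count_parameters(conv) == 4  # 3 weights + 1 bias

    def test_count_invariant_under_forward(self, rng):
        model = build_model(reduced_cfg())
        before = count_parameters(model)
        model(rng.standard_normal((1, 3, 64, 64)))
        assert count_parameters(model) == before


class TestAblationSuite:
    def test_eight_unique_named_variants(self):
        suite = make_ablation_suite(reduced_cfg())
        assert [v.name for v in suite] == list(ABLATION_NAMES)
        assert len({v.name for v in suite}) == 8

    def test_baseline_has_no_refinement_blocks(self):
        baseline = make_ablation_suite(reduced_cfg())[0]
        assert baseline.config.use_wcf is False
        assert not baseline.config.wtconv_stages
        assert not baseline.config.lrfa_stages

    def test_parameter_counts_strictly_ordered_by_module_inclusion(self):
        suite = make_ablation_suite(reduced_cfg())
        counts = {v.name: count_parameters(build_model(v.config)) for v in suite}
        sets = {v.name: v.module_set for v in suite}
        for a in suite:
            for b in suite:
                if sets[a.name] < sets[b.name]:
                    assert counts[a.name] < counts[b.name], (a.name, b.name)

    def test_every_variant_completes_a_forward_pass(self, rng):
        x = rng.standard_normal((1, 3, 64, 64))
        for variant in make_ablation_suite(reduced_cfg()):
            out = build_model(variant.config)(x)
            assert out.shape == (1, 1, 64, 64)


class TestCheckpointing:
    def test_round_trip_restores_weights_and_config(self, tmp_path, rng):
        model = build_model(reduced_cfg(seed=9))
        x = rng.standard_normal((1, 3, 64, 64))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, optimizer_state=None, epoch=17)
        restored, opt_state, epoch = load_checkpoint(path)
        assert epoch == 17 and opt_state is None
        assert restored.cfg == model.cfg
        np.testing.assert_array_equal(restored(x).data, model(x).data)

    def test_magic_string_guard(self, tmp_path):
        bad = tmp_path / "bad.npz"
        np.savez(bad, magic=np.array("OTHER.v9"), config=np.array("{}"),
                 epoch=np.asarray(0))
        with pytest.raises(ValidationError, match="magic"):
            load_checkpoint(bad)
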