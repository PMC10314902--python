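"""Fusion model: token fusion, modality regimes, vision dropout, masking."""

import numpy as np
import pytest

from icufusion.model import (
    ModelConfig,
    MultimodalTransformer,
    apply_vision_dropout,
    mask_feature_batch,
    mask_parameters,
)
from icufusion.nn import Tensor
from icufusion.tokenizer import FeatureMatrix
from icufusion.types import PatientSample, TokenBlock


@pytest.fixture()
def model(tiny_model_cfg) -> MultimodalTransformer:
    return MultimodalTransformer(tiny_model_cfg, seed=0)


def _sample(rng, cfg: ModelConfig, label=1) -> PatientSample:
    spec = cfg.image_spec
    img = rng.normal(size=(spec.channels, spec.height, spec.width))
    feats = FeatureMatrix(
        rng.normal(size=(cfg.n_features, cfg.T)),
        [f"f{i}" for i in range(cfg.n_features)],
        ["hr", "hr", "rr", "rr", "spo2"],
    )
    return PatientSample(image=img, clinical=feats, label=label,
                         patient_id="p1", stay_id="s1", image_id="i1")


class TestFuse:
    def test_fused_length_is_n_plus_m_plus_one(self, model, rng, tiny_model_cfg):
        D = tiny_model_cfg.fusion.dim
        z_img = TokenBlock(Tensor(rng.normal(size=(model.N, D))), "image")
        z_cp = TokenBlock(Tensor(rng.normal(size=(model.M, D))), "clinical")
        fused = model.fuse(z_img, z_cp)
        assert fused.shape == (model.N + model.M + 1, D)

    def test_cls_at_index_zero_and_position_tokens_added(self, model, rng, tiny_model_cfg):
        D = tiny_model_cfg.fusion.dim
        z_img = TokenBlock(Tensor(np.zeros((model.N, D))), "image")
        z_cp = TokenBlock(Tensor(np.zeros((model.M, D))), "clinical")
        fused = model.fuse(z_img, z_cp)
        assert np.allclose(fused.data[0], model.cls_token.data)
        # with zero inputs the remaining rows are exactly the position tokens
        assert np.allclose(fused.data[1:], model.pos_tokens.data)

    def test_width_mismatch_errors(self, model, rng):
        z_img = TokenBlock(Tensor(rng.normal(size=(model.N, 16))), "image")
        z_cp = TokenBlock(Tensor(rng.normal(size=(model.M, 8))), "clinical")
        with pytest.raises(ValueError):
            model.fuse(z_img, z_cp)


class TestForward:
    def test_probability_strictly_inside_unit_interval(self, model, rng, tiny_model_cfg):
        for mode in ("cp_only", "cxr_only", "combined"):
            pred = model.forward(_sample(rng, tiny_model_cfg), mode=mode)
            assert 0.0 < pred.risk < 1.0
            assert pred.mode == mode

    def test_cp_only_ignores_image_content(self, model, rng, tiny_model_cfg):
        s1 = _sample(rng, tiny_model_cfg)
        s2 = _sample(rng, tiny_model_cfg)
        s2.clinical = s1.clinical
        a = model.forward(s1, mode="cp_only").risk
        b = model.forward(s2, mode="cp_only").risk
        assert a == b

    def test_cxr_only_ignores_clinical_content(self, model, rng, tiny_model_cfg):
        s1 = _sample(rng, tiny_model_cfg)
        s2 = _sample(rng, tiny_model_cfg)
        s2.image = s1.image
        assert model.forward(s1, "cxr_only").risk == model.forward(s2, "cxr_only").risk

    def test_inference_is_deterministic(self, model, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        assert model.forward(s, "combined").risk == model.forward(s, "combined").risk

    def test_cp_only_equals_combined_on_zero_image(self, model, rng, tiny_model_cfg):
        """The clinical-only regime is exactly the combined regime fed the
        canonical zero image."""
        s = _sample(rng, tiny_model_cfg)
        zeroed = PatientSample(
            image=np.zeros_like(s.image), clinical=s.clinical, label=s.label
        )
        a = model.forward(s, mode="cp_only").risk
        b = model.forward(zeroed, mode="combined").risk
        assert a == pytest.approx(b, abs=1e-6)

    def test_missing_image_in_cxr_only_errors(self, model, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        s.image = None
        with pytest.raises(ValueError):
            model.forward(s, mode="cxr_only")
        assert 0 < model.forward(s, mode="cp_only").risk < 1

    def test_sequence_length_conserved_through_fusion(self, model, rng, tiny_model_cfg):
        z = Tensor(rng.normal(size=(2, model.N + model.M + 1, tiny_model_cfg.fusion.dim)))
        out = model.fusion(z)
        assert out.shape == z.shape

    def test_gradients_reach_both_modalities(self, model, rng, tiny_model_cfg):
        from icufusion.training import bce_loss_tensor

        patches = rng.normal(size=(4, model.N, tiny_model_cfg.image_spec.patch_dim))
        feats = rng.normal(size=(4, tiny_model_cfg.n_features, tiny_model_cfg.T))
        p = model.forward_batch(patches, feats, mode="combined")
        loss = bce_loss_tensor(p, np.array([0, 1, 0, 1]))
        model.zero_grad()
        loss.backward()
        assert np.abs(model.backbone.patch_embed.weight.grad).max() > 0
        assert np.abs(model.clinical_proj.weight.grad).max() > 0


class TestVisionDropout:
    def test_p_zero_keeps_batch_p_one_zeroes_all(self, rng):
        batch = rng.normal(size=(8, 4, 12))
        assert np.array_equal(apply_vision_dropout(batch, 0.0, rng), batch)
        assert not apply_vision_dropout(batch, 1.0, rng).any()

    def test_inference_time_call_is_an_error(self, rng):
        with pytest.raises(RuntimeError):
            apply_vision_dropout(np.zeros((2, 1, 1)), 0.3, rng, training=False)

    def test_whole_image_granularity(self, rng):
        batch = np.ones((200, 4, 12))
        out = apply_vision_dropout(batch, 0.5, rng)
        per_sample = out.reshape(200, -1).sum(axis=1)
        assert set(np.unique(per_sample)) <= {0.0, 48.0}

    def test_zeroed_fraction_within_three_sigma(self, rng):
        """Binomial oracle: fraction ~ B(n, 0.3)/n at n = 10,000."""
        n, p = 10_000, 0.30
        batch = np.ones((n, 2, 3))
        out = apply_vision_dropout(batch, p, np.random.default_rng(42))
        frac = (out.reshape(n, -1).sum(axis=1) == 0).mean()
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * sigma

    def test_pixel_mode_drops_entries_not_images(self, rng):
        batch = np.ones((4, 10, 10))
        out = apply_vision_dropout(batch, 0.3, np.random.default_rng(0), mode="pixel")
        flat = out.reshape(4, -1)
        assert ((flat > 0).any(axis=1) & (flat == 0).any(axis=1)).all()


class TestMaskParameters:
    def test_empty_mask_is_identity(self, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        out = mask_parameters(s, set())
        assert np.array_equal(out.clinical.features, s.clinical.features)

    def test_masking_all_items_zeroes_features(self, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        out = mask_parameters(s, {"hr", "rr", "spo2"})
        assert not out.clinical.features.any()
        assert np.array_equal(out.image, s.image)

    def test_only_targeted_rows_change(self, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        out = mask_parameters(s, {"hr"})
        assert not out.clinical.features[:2].any()
        assert np.array_equal(out.clinical.features[2:], s.clinical.features[2:])

    def test_unknown_item_errors(self, rng, tiny_model_cfg):
        with pytest.raises(KeyError):
            mask_parameters(_sample(rng, tiny_model_cfg), {"nope"})

    def test_batched_masking_matches_per_sample(self, rng, tiny_model_cfg):
        s = _sample(rng, tiny_model_cfg)
        batch = s.clinical.features[None].repeat(3, axis=0)
        out = mask_feature_batch(batch, s.clinical.source_item, {"rr"})
        single = mask_parameters(s, {"rr"}).clinical.features
        assert np.allclose(out[0], single)


def test_checkpoint_round_trip(tmp_path, model, rng, tiny_model_cfg):
    s = _sample(rng, tiny_model_cfg)
    before = model.forward(s, "combined").risk
    model.save(tmp_path / "ckpt")
    again = MultimodalTransformer.load(tmp_path / "ckpt")
    assert again.forward(s, "combined").risk == pytest.approx(before, abs=1e-7)
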