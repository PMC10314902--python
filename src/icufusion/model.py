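"""Token-level multimodal fusion of image and clinical tokens.

The model concatenates N image tokens (vision backbone) and M = T clinical
tokens (linear projection of the hourly feature vectors), adds N + M
learnable position tokens element-wise, prepends a learnable CLS token, runs
the sequence through a multi-head self-attention encoder, and maps the CLS
output through a small MLP with a sigmoid to the predicted in-hospital
death risk (labels code 1 = died in hospital).

Unimodal regimes reuse the same network: the clinical-only regime feeds the
canonical zero image, the radiograph-only regime zeroes the clinical feature
matrix before projection.  Vision dropout — zeroing a sample's image with
probability ``p_vdo`` during training — keeps the fusion encoder from
relying exclusively on the vision backbone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .images import BackboneConfig, ImageSpec, VisionBackbone, patchify, zero_image
from .nn import Linear, Module, Tensor, TransformerEncoder, concat
from .tokenizer import FeatureMatrix
from .types import PatientSample, Prediction, TokenBlock

__all__ = [
    "FusionConfig",
    "ModelConfig",
    "MultimodalTransformer",
    "apply_vision_dropout",
    "mask_parameters",
    "MODES",
]

MODES = ("cp_only", "cxr_only", "combined")


@dataclass(frozen=True)
class FusionConfig:
    """Fusion encoder geometry and the vision-dropout probability."""

    dim: int = 64
    depth: int = 2
    heads: int = 4
    mlp_hidden: int = 64  # hidden width of the prediction head
    mlp_ratio: int = 4  # encoder MLP hidden = mlp_ratio * dim
    p_vdo: float = 0.30
    vdo_mode: str = "sample"  # "sample": whole-image zeroing; "pixel": i.i.d. pixels

    def __post_init__(self):
        if not 0.0 <= self.p_vdo <= 1.0:
            raise ValueError("p_vdo must lie in [0, 1]")
        if self.vdo_mode not in ("sample", "pixel"):
            raise ValueError(f"unknown vdo_mode {self.vdo_mode!r}")


@dataclass(frozen=True)
class ModelConfig:
    image_spec: ImageSpec = field(default_factory=ImageSpec)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_features: int = 27  # F of the encoded clinical matrix
    T: int = 48

    def __post_init__(self):
        if self.backbone.dim != self.fusion.dim:
            raise ValueError("backbone and fusion token widths must match")

    def to_dict(self) -> dict:
        return {
            "image_spec": asdict(self.image_spec),
            "backbone": asdict(self.backbone),
            "fusion": asdict(self.fusion),
            "n_features": self.n_features,
            "T": self.T,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        spec = d["image_spec"].copy()
        spec["norm_mean"] = tuple(spec["norm_mean"])
        spec["norm_std"] = tuple(spec["norm_std"])
        return cls(
            image_spec=ImageSpec(**spec),
            backbone=BackboneConfig(**d["backbone"]),
            fusion=FusionConfig(**d["fusion"]),
            n_features=d["n_features"],
            T=d["T"],
        )


class MultimodalTransformer(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        D = cfg.fusion.dim
        self.backbone = VisionBackbone(cfg.image_spec, cfg.backbone, rng)
        self.clinical_proj = Linear(cfg.n_features, D, rng)
        self.N = cfg.image_spec.n_tokens
        self.M = cfg.T
        self.pos_tokens = Tensor(
            rng.normal(0.0, 0.02, size=(self.N + self.M, D)), requires_grad=True
        )
        self.cls_token = Tensor(rng.normal(0.0, 0.02, size=(D,)), requires_grad=True)
        self.fusion = TransformerEncoder(
            D, cfg.fusion.depth, cfg.fusion.heads, cfg.fusion.mlp_ratio * D, rng
        )
        self.head_fc1 = Linear(D, cfg.fusion.mlp_hidden, rng)
        self.head_fc2 = Linear(cfg.fusion.mlp_hidden, 1, rng)

    # ----------------------------------------------------------------- fusion
    def fuse(self, z_cxr: TokenBlock, z_cp: TokenBlock) -> Tensor:
        """Concatenate image-then-clinical tokens, add position tokens, prepend CLS.

        Returns the fused (N + M + 1, D) sequence with CLS at index 0.
        """
        if z_cxr.D != z_cp.D:
            raise ValueError(f"token width mismatch: {z_cxr.D} vs {z_cp.D}")
        if z_cxr.count + z_cp.count != self.pos_tokens.shape[0]:
            raise ValueError(
                f"position tokens cover {self.pos_tokens.shape[0]} positions, "
                f"got {z_cxr.count}+{z_cp.count} tokens"
            )
        seq = concat([z_cxr.tokens, z_cp.tokens], axis=0) + self.pos_tokens
        cls = self.cls_token.reshape(1, -1)
        return concat([cls, seq], axis=0)

    # ----------------------------------------------------------- batched path
    def forward_batch(
        self, patches: np.ndarray, features: np.ndarray, mode: str = "combined"
    ) -> Tensor:
        """Predict death risk for a batch.

        patches: (B, N, patch_dim) preprocessed image patches.
        features: (B, F, T) encoded clinical matrices.
        Returns a (B,) Tensor of probabilities in (0, 1).
        """
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        B = patches.shape[0]
        ones_b = Tensor(np.zeros((B, 1, 1)))
        if mode == "cp_only":
            # the zero image is one canonical input: encode once, broadcast
            zeros = Tensor(np.zeros((1,) + patches.shape[1:]))
            z_img = self.backbone.encode_patches(zeros) + ones_b
        else:
            z_img = self.backbone.encode_patches(Tensor(patches))  # (B, N, D)
        if mode == "cxr_only":
            zeros = Tensor(np.zeros((1, features.shape[2], features.shape[1])))
            z_cp = self.clinical_proj(zeros) + ones_b
        else:
            feats = Tensor(np.swapaxes(features, 1, 2))  # (B, T, F)
            z_cp = self.clinical_proj(feats)  # (B, T, D)
        seq = concat([z_img, z_cp], axis=1) + self.pos_tokens
        cls = self.cls_token.reshape(1, 1, -1) + Tensor(np.zeros((B, 1, seq.shape[2])))
        fused = concat([cls, seq], axis=1)  # (B, N+M+1, D)
        out = self.fusion(fused)
        h = self.head_fc1(out[:, 0, :]).gelu()
        logits = self.head_fc2(h).reshape(B)
        return logits.sigmoid()

    # ------------------------------------------------------------ sample path
    def _sample_inputs(self, sample: PatientSample, mode: str):
        spec = self.cfg.image_spec
        if sample.image is None:
            if mode == "cxr_only":
                raise ValueError("cxr_only mode requires an image in the sample")
            img = np.zeros((spec.channels, spec.height, spec.width))
        else:
            img = sample.image
        patches = patchify(img, spec.patch_size)[None]
        feats = sample.clinical.features[None]
        return patches, feats

    def forward(self, sample: PatientSample, mode: str = "combined") -> Prediction:
        """Single-sample inference; deterministic for fixed weights and input."""
        patches, feats = self._sample_inputs(sample, mode)
        p = self.forward_batch(patches, feats, mode=mode)
        return Prediction(risk=float(p.data[0]), mode=mode)

    def predict_scores(
        self, patches: np.ndarray, features: np.ndarray, mode: str = "combined",
        batch_size: int = 64,
    ) -> np.ndarray:
        """Vectorised inference-mode scoring; returns (n,) death-risk scores."""
        from .nn import no_grad

        out = []
        with no_grad():
            for i in range(0, patches.shape[0], batch_size):
                p = self.forward_batch(
                    patches[i : i + batch_size], features[i : i + batch_size], mode=mode
                )
                out.append(p.data.copy())
        return np.concatenate(out).astype(np.float64)

    # -------------------------------------------------------------- persistence
    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write weights (.npz) plus config and optional metadata (.json),
        e.g. the schema hash the model was trained against."""
        path = Path(path)
        state = self.state_dict()
        np.savez(path.with_suffix(".npz"), **state)
        doc = {"config": self.cfg.to_dict(), "meta": meta or {}}
        path.with_suffix(".json").write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultimodalTransformer":
        path = Path(path)
        doc = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig.from_dict(doc["config"])
        model = cls(cfg, seed=0)
        with np.load(path.with_suffix(".npz")) as st:
            model.load_state_dict({k: st[k] for k in st.files})
        return model

    @staticmethod
    def load_meta(path: str | Path) -> dict:
        doc = json.loads(Path(path).with_suffix(".json").read_text())
        return doc.get("meta", {})


def apply_vision_dropout(
    patches: np.ndarray,
    p_vdo: float,
    rng: np.random.Generator,
    training: bool = True,
    mode: str = "sample",
) -> np.ndarray:
    """Zero each sample's image patches independently with probability p_vdo.

    Training-time only.  ``mode="sample"`` zeroes whole images (the default
    reading: a modality is removed or present); ``mode="pixel"`` zeroes
    i.i.d. patch entries instead.
    """
    if not training:
        raise RuntimeError("vision dropout is a training-time operation")
    if not 0.0 <= p_vdo <= 1.0:
        raise ValueError("p_vdo must lie in [0, 1]")
    out = patches.copy()
    if mode == "sample":
        drop = rng.random(patches.shape[0]) < p_vdo
        out[drop] = 0.0
    elif mode == "pixel":
        out[rng.random(patches.shape) < p_vdo] = 0.0
    else:
        raise ValueError(f"unknown vision-dropout mode {mode!r}")
    return out


def mask_parameters(sample: PatientSample, items_to_mask: set[str]) -> PatientSample:
    """Zero every encoded feature row derived from the masked items.

    Acts on the encoded feature matrix (no re-imputation), mirroring
    inference-time unavailability of a parameter; the image is untouched.
    """
    fm: FeatureMatrix = sample.clinical
    known = set(fm.source_item)
    unknown = set(items_to_mask) - known
    if unknown:
        raise KeyError(f"unknown items: {sorted(unknown)}")
    masked = fm.copy()
    rows = [i for i, src in enumerate(fm.source_item) if src in items_to_mask]
    masked.features[rows, :] = 0.0
    return PatientSample(
        image=sample.image,
        clinical=masked,
        label=sample.label,
        patient_id=sample.patient_id,
        stay_id=sample.stay_id,
        image_id=sample.image_id,
    )


def mask_feature_batch(
    features: np.ndarray, source_item: list[str], items_to_mask: set[str]
) -> np.ndarray:
    """Batched variant of :func:`mask_parameters` on a (B, F, T) array."""
    known = set(source_item)
    unknown = set(items_to_mask) - known
    if unknown:
        raise KeyError(f"unknown items: {sorted(unknown)}")
    out = features.copy()
    rows = [i for i, src in enumerate(source_item) if src in items_to_mask]
    out[:, rows, :] = 0.0
    return out
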