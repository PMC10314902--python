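"""Shared lightweight containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = ["TokenBlock", "PatientSample", "Prediction"]


@dataclass
class TokenBlock:
    """A count x D block of latent tokens tagged by modality."""

    tokens: Tensor  # (count, D)
    modality: str  # "clinical" | "image"

    def __post_init__(self):
        if self.modality not in ("clinical", "image"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.tokens.ndim != 2:
            raise ValueError("token block must be 2-d (count, D)")
        if not np.isfinite(self.tokens.data).all():
            raise ValueError("token block contains non-finite values")

    @property
    def count(self) -> int:
        return self.tokens.shape[0]

    @property
    def D(self) -> int:
        return self.tokens.shape[1]


@dataclass
class PatientSample:
    """One paired record: preprocessed image (or None), encoded clinical
    features, binary in-hospital outcome (1 = died, 0 = discharged alive)."""

    image: np.ndarray | None  # (C, H, W) preprocessed, or None when absent
    clinical: "object"  # FeatureMatrix
    label: int
    patient_id: str = ""
    stay_id: str = ""
    image_id: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (alive) or 1 (died)")


@dataclass
class Prediction:
    """Predicted in-hospital death risk, strictly inside (0, 1)."""

    risk: float
    mode: str  # "cp_only" | "cxr_only" | "combined"

    def __post_init__(self):
        if not 0.0 < self.risk < 1.0:
            raise ValueError("risk must lie strictly in (0, 1)")
        if self.mode not in ("cp_only", "cxr_only", "combined"):
            raise ValueError(f"unknown mode {self.mode!r}")
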