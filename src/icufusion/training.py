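"""Loss, schedule, cohort splitting and the two-phase training protocol.

Training minimises binary cross-entropy with AdamW under per-epoch cosine
annealing from ``lr_start`` to ``lr_end``.  Three regimes share one
architecture: clinical-parameters-only (images always zeroed),
radiographs-only (clinical features zeroed), and combined.  The combined
phase resumes from the best clinical-only checkpoint — selected by
validation AUROC — and trains with vision dropout, so the fusion encoder
first learns the clinical signal and only then receives images.

Cohorts are split 72/8/20 at the patient level (every radiograph of a
patient lands in one split), stratified by in-hospital death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ScoredSet, roc_auc
from .model import MODES, MultimodalTransformer, apply_vision_dropout
from .nn import AdamW, Tensor

__all__ = [
    "TrainConfig",
    "CheckpointIndex",
    "CohortArrays",
    "bce_loss",
    "bce_loss_tensor",
    "cosine_lr",
    "split_cohort",
    "train_phase",
    "select_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  The defaults mirror the full-scale recipe
    (200 epochs, AdamW 5e-6 -> 1e-7 cosine); small synthetic studies
    override epochs and learning rates to their own scale."""

    epochs: int = 200
    lr_start: float = 5e-6
    lr_end: float = 1e-7
    batch_size: int = 16
    weight_decay: float = 0.01
    seed: int = 0
    phase: str = "combined"
    p_vdo: float = 0.30
    # combined phase only: lr multiplier for the parameters resumed from the
    # clinical-only checkpoint (everything but the vision backbone).  Below 1,
    # the warm parameters fine-tune gently while the cold backbone learns fast.
    warm_lr_scale: float = 1.0
    # per-step exponential moving average of the weights; the per-epoch
    # checkpoint (and its validation AUROC) is the EMA state, which smooths
    # both overfitting spikes and checkpoint-selection noise.  0 disables.
    ema_decay: float = 0.995

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr_end < self.lr_start:
            raise ValueError("lr_end must be below lr_start")
        if self.phase not in MODES:
            raise ValueError(f"unknown phase {self.phase!r}")


def bce_loss(p, y) -> float:
    """Mean negative binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def bce_loss_tensor(p: Tensor, y: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Differentiable batch-mean BCE; eps guards the log at saturation."""
    y = np.asarray(y, dtype=np.float64)
    yt = Tensor(y)
    loss = -(yt * (p + eps).log() + (1.0 - yt) * ((1.0 - p) + eps).log())
    return loss.mean()


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Per-epoch cosine annealing from lr_start (epoch 0) to lr_end (last)."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if cfg.epochs == 1:
        return cfg.lr_start
    frac = epoch / (cfg.epochs - 1)
    return cfg.lr_end + 0.5 * (cfg.lr_start - cfg.lr_end) * (1.0 + math.cos(math.pi * frac))


# --------------------------------------------------------------- cohort split

def split_cohort(
    patient_ids: list[str],
    patient_labels: dict[str, int] | None = None,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    seed: int = 0,
    split_file: str | Path | None = None,
) -> dict[str, str]:
    """Assign each patient to train/val/test, stratified by outcome.

    All samples of a patient share one split.  Within each outcome stratum
    patients are shuffled and allocated by largest-remainder rounding, so
    split sizes match the fractions to within rounding.  A split file
    (CSV ``patient_id,set``) overrides random assignment.
    """
    unique = list(dict.fromkeys(patient_ids))
    if split_file is not None:
        df = pd.read_csv(split_file, dtype=str)
        mapping = dict(zip(df["patient_id"], df["set"]))
        missing = [p for p in unique if p not in mapping]
        if missing:
            raise ValueError(f"split file lacks patients: {missing[:5]}")
        bad = set(mapping.values()) - {"train", "val", "test"}
        if bad:
            raise ValueError(f"split file has unknown sets: {sorted(bad)}")
        return {p: mapping[p] for p in unique}
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if patient_labels is None:
        patient_labels = {p: 0 for p in unique}
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    for stratum in sorted(set(patient_labels[p] for p in unique)):
        members = [p for p in unique if patient_labels[p] == stratum]
        members = [members[i] for i in rng.permutation(len(members))]
        n = len(members)
        ideal = [f * n for f in fractions]
        counts = [int(x) for x in ideal]
        remainders = sorted(
            range(3), key=lambda i: (-(ideal[i] - counts[i]), i)
        )
        for i in remainders[: n - sum(counts)]:
            counts[i] += 1
        start = 0
        for name, c in zip(names, counts):
            for p in members[start : start + c]:
                assignment[p] = name
            start += c
    return assignment


# ------------------------------------------------------------- training arrays

@dataclass
class CohortArrays:
    """Dense arrays for a split: image patches, clinical features, labels."""

    patches: np.ndarray  # (n, N, patch_dim)
    features: np.ndarray  # (n, F, T)
    labels: np.ndarray  # (n,)
    patient_ids: np.ndarray
    sample_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass
class CheckpointIndex:
    """Per-epoch validation AUROC with in-memory weight snapshots."""

    entries: list[tuple[int, float, str]] = field(default_factory=list)
    states: dict[str, dict] = field(default_factory=dict)
    losses: list[float] = field(default_factory=list)

    def add(self, epoch: int, val_auroc: float, state: dict, loss: float) -> None:
        key = f"epoch{epoch:04d}"
        self.entries.append((epoch, float(val_auroc), key))
        self.states[key] = state
        self.losses.append(float(loss))

    def best(self) -> tuple[int, float, str]:
        if not self.entries:
            raise ValueError("empty checkpoint index")
        return max(self.entries, key=lambda e: (e[1], -e[0]))


def select_checkpoint(idx: CheckpointIndex) -> str:
    """Key of the highest-validation-AUROC epoch; ties go to the earliest."""
    return idx.best()[2]


def train_phase(
    model: MultimodalTransformer,
    train: CohortArrays,
    val: CohortArrays,
    cfg: TrainConfig,
    init_state: dict | None = None,
    verbose: bool = False,
) -> CheckpointIndex:
    """Run one training phase and index every epoch by validation AUROC.

    cp_only trains with images always zeroed, cxr_only with clinical
    features zeroed; combined requires the best clinical-only checkpoint as
    ``init_state`` and applies vision dropout at ``cfg.p_vdo``.  Fully
    deterministic given the config seed.
    """
    if cfg.phase == "combined":
        if init_state is None:
            raise ValueError("combined phase requires an initial checkpoint state")
        model.load_state_dict(init_state)
    elif init_state is not None:
        model.load_state_dict(init_state)
    rng = np.random.default_rng(cfg.seed)
    # a zeroed modality provides no signal: freeze its branch so unimodal
    # phases leave it at its checkpointed state instead of noise-fitting it
    frozen_prefix = {"cp_only": "backbone.", "cxr_only": "clinical_proj."}.get(cfg.phase)
    named = [
        (name, p) for name, p in model.named_parameters()
        if frozen_prefix is None or not name.startswith(frozen_prefix)
    ]
    if cfg.phase == "combined" and cfg.warm_lr_scale != 1.0:
        cold = [p for n, p in named if n.startswith("backbone.")]
        warm = [p for n, p in named if not n.startswith("backbone.")]
        opts = [
            (AdamW(cold, weight_decay=cfg.weight_decay), 1.0),
            (AdamW(warm, weight_decay=cfg.weight_decay), cfg.warm_lr_scale),
        ]
    else:
        opts = [(AdamW([p for _, p in named], weight_decay=cfg.weight_decay), 1.0)]
    index = CheckpointIndex()
    vdo_mode = model.cfg.fusion.vdo_mode
    params = dict(model.named_parameters())
    ema = {k: p.data.copy() for k, p in params.items()} if cfg.ema_decay else None
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        order = rng.permutation(train.n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, train.n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            patches = train.patches[idx]
            feats = train.features[idx]
            if cfg.phase == "combined" and cfg.p_vdo > 0:
                patches = apply_vision_dropout(
                    patches, cfg.p_vdo, rng, training=True, mode=vdo_mode
                )
            p = model.forward_batch(patches, feats, mode=cfg.phase)
            loss = bce_loss_tensor(p, train.labels[idx])
            model.zero_grad()
            loss.backward()
            for opt, scale in opts:
                opt.step(lr=lr * scale)
            if ema is not None:
                d = cfg.ema_decay
                for k, pr in params.items():
                    ema[k] = d * ema[k] + (1.0 - d) * pr.data
            epoch_loss += float(loss.data)
            n_batches += 1
        # the epoch's checkpoint is the EMA state; validate on it
        if ema is not None:
            raw = {k: p.data.copy() for k, p in params.items()}
            model.load_state_dict(ema)
        val_scores = model.predict_scores(val.patches, val.features, mode=cfg.phase)
        val_auroc = roc_auc(ScoredSet(val_scores, val.labels))
        index.add(epoch, val_auroc, model.state_dict(), epoch_loss / max(n_batches, 1))
        if ema is not None:
            model.load_state_dict(raw)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {epoch_loss / max(n_batches, 1):.4f}  "
                f"val_auroc {val_auroc:.4f}  lr {lr:.2e}"
            )
    return index
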