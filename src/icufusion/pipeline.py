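"""End-to-end assembly: raw paired cohort -> splits -> trained regimes.

This is the orchestration layer used by the CLI, the examples and the
acceptance study: split patients 72/8/20, grid and impute the clinical
series, fit the feature scaler on the training split only, encode, patch
the preprocessed images, then train the three modality regimes
(clinical-only, radiograph-only, combined-resuming-from-clinical) and
score the test split under each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import ImageSpec, patchify, preprocess_image
from .model import ModelConfig, MultimodalTransformer
from .schema import ParameterSchema, drop_all_missing_items
from .tokenizer import (
    ClinicalMatrix,
    FeatureScaler,
    bin_events,
    encode,
    impute,
)
from .training import (
    CohortArrays,
    TrainConfig,
    select_checkpoint,
    split_cohort,
    train_phase,
)

__all__ = ["StudySplits", "assemble_study", "train_regime",
           "default_study_model_config", "run_three_regimes", "run_replicate"]


def _get(sample, key):
    if isinstance(sample, dict):
        return sample[key]
    return getattr(sample, key)


@dataclass
class StudySplits:
    train: CohortArrays
    val: CohortArrays
    test: CohortArrays
    schema: ParameterSchema  # usable items only (fully missing items dropped)
    scaler: FeatureScaler
    image_spec: ImageSpec
    source_item: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.schema.n_features


def assemble_study(
    samples: list,
    schema: ParameterSchema,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    T: int = 48,
    patch_size: int = 16,
    split_file=None,
) -> StudySplits:
    """Split, impute, encode and patch a paired cohort.

    Items missing for every stay are dropped from the schema first; the
    feature scaler is fitted on the training split only and applied to all
    three splits.
    """
    usable = drop_all_missing_items(schema)
    img0 = _get(samples[0], "image")
    spec = ImageSpec(height=img0.shape[0], width=img0.shape[1], patch_size=patch_size)

    patient_ids = [_get(s, "patient_id") for s in samples]
    labels = {pid: 0 for pid in patient_ids}
    for s in samples:
        pid = _get(s, "patient_id")
        labels[pid] = max(labels[pid], int(_get(s, "label")))
    assignment = split_cohort(patient_ids, labels, fractions, seed=seed,
                              split_file=split_file)

    # one matrix per stay (stays shared by several radiographs are gridded once)
    stay_matrices: dict[str, ClinicalMatrix] = {}
    for s in samples:
        stay = _get(s, "stay_id")
        if stay in stay_matrices:
            continue
        if not isinstance(s, dict) and getattr(s, "matrix_values", None) is not None:
            # already gridded (synthetic fast path): select the usable rows
            rows = [s.item_names.index(name) for name in usable.names]
            binned = ClinicalMatrix(
                s.matrix_values[rows, :T], s.matrix_observed[rows, :T], usable.names
            )
        else:
            binned = bin_events(_get(s, "stream"), usable, T=T)
        stay_matrices[stay] = impute(binned, usable)

    train_mats = [
        stay_matrices[_get(s, "stay_id")]
        for s in samples
        if assignment[_get(s, "patient_id")] == "train"
    ]
    scaler = FeatureScaler.fit(train_mats, usable)
    _, source_item = usable.feature_layout()

    buckets = {name: [] for name in ("train", "val", "test")}
    for s in samples:
        buckets[assignment[_get(s, "patient_id")]].append(s)

    def build(split_samples) -> CohortArrays:
        n = len(split_samples)
        # float32: matches the training engine's precision at half the memory
        patches = np.empty((n, spec.n_tokens, spec.patch_dim), dtype=np.float32)
        features = np.empty((n, usable.n_features, T), dtype=np.float32)
        y = np.empty(n, dtype=int)
        pids = np.empty(n, dtype=object)
        sids = np.empty(n, dtype=object)
        for i, s in enumerate(split_samples):
            img = preprocess_image(_get(s, "image"), spec)
            patches[i] = patchify(img, spec.patch_size)
            fm = encode(stay_matrices[_get(s, "stay_id")], usable, scaler)
            features[i] = fm.features
            y[i] = int(_get(s, "label"))
            pids[i] = _get(s, "patient_id")
            sids[i] = _get(s, "image_id")
        return CohortArrays(patches, features, y, pids, sids)

    return StudySplits(
        train=build(buckets["train"]),
        val=build(buckets["val"]),
        test=build(buckets["test"]),
        schema=usable,
        scaler=scaler,
        image_spec=spec,
        source_item=source_item,
    )


def train_regime(
    splits: StudySplits,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_state: dict | None = None,
    verbose: bool = False,
):
    """Train one regime and return (model-at-best-checkpoint, index)."""
    model = MultimodalTransformer(model_cfg, seed=train_cfg.seed)
    index = train_phase(model, splits.train, splits.val, train_cfg,
                        init_state=init_state, verbose=verbose)
    model.load_state_dict(index.states[select_checkpoint(index)])
    return model, index


def default_study_model_config(splits: StudySplits) -> ModelConfig:
    """The CPU-scale study geometry: width 64, depth 2 in both encoders."""
    from .images import BackboneConfig
    from .model import FusionConfig

    return ModelConfig(
        image_spec=splits.image_spec,
        backbone=BackboneConfig(depth=2, dim=64, heads=4, mlp_ratio=2),
        fusion=FusionConfig(dim=64, depth=2, heads=4, mlp_hidden=64, mlp_ratio=2),
        n_features=splits.n_features,
        T=48,
    )


def run_three_regimes(
    splits: StudySplits,
    model_cfg: ModelConfig,
    epochs_unimodal: tuple[int, int] = (3, 3),
    epochs_combined: int = 12,
    lr_start: float = 1e-3,
    lr_combined: float = 1.5e-3,
    lr_end: float = 1e-4,
    batch_size: int = 16,
    warm_lr_scale: float = 1.0,
    seed: int = 0,
    p_vdo: float = 0.30,
    verbose: bool = False,
) -> dict:
    """The full protocol: cp_only and cxr_only from scratch, then combined
    resuming from the best clinical-only checkpoint with vision dropout.

    The unimodal regimes converge within a few epochs at this scale, so the
    combined phase gets the larger budget; it runs with a higher base rate
    for the cold vision backbone and a scaled-down rate for the resumed
    (warm) parameters.  Returns models and test-set death-risk scores per
    regime.
    """
    def cfg(phase, epochs, lr, warm=1.0):
        return TrainConfig(
            epochs=epochs, lr_start=lr, lr_end=lr_end,
            batch_size=batch_size, seed=seed, phase=phase, p_vdo=p_vdo,
            warm_lr_scale=warm,
        )

    out: dict = {"labels": splits.test.labels}
    cp_model, cp_idx = train_regime(
        splits, model_cfg, cfg("cp_only", epochs_unimodal[0], lr_start),
        verbose=verbose,
    )
    cxr_model, _ = train_regime(
        splits, model_cfg, cfg("cxr_only", epochs_unimodal[1], lr_start),
        verbose=verbose,
    )
    best_cp_state = cp_idx.states[select_checkpoint(cp_idx)]
    comb_model, _ = train_regime(
        splits, model_cfg,
        cfg("combined", epochs_combined, lr_combined, warm=warm_lr_scale),
        init_state=best_cp_state, verbose=verbose,
    )
    out["models"] = {"cp_only": cp_model, "cxr_only": cxr_model, "combined": comb_model}
    for mode, model in out["models"].items():
        out[mode] = model.predict_scores(
            splits.test.patches, splits.test.features, mode=mode
        )
    return out


def run_replicate(
    seed: int,
    n_patients: int = 2000,
    n_boot: int = 1000,
    verbose: bool = False,
) -> dict:
    """One full synthetic study replicate under the default conditions.

    Generates a paired cohort, splits 72/8/20, trains the three regimes and
    returns test AUROCs, paired-bootstrap p-values for the combined model
    against each unimodal model, the trained models and the splits.
    """
    from .evaluation import ScoredSet, bootstrap_p_diff, roc_auc
    from .schema import default_schema
    from .synthetic import CohortConfig, generate_cohort, oracle_auc

    cohort_cfg = CohortConfig(n_patients=n_patients, seed=seed)
    samples, truth = generate_cohort(cohort_cfg)
    splits = assemble_study(samples, default_schema(), seed=seed)
    res = run_three_regimes(
        splits, default_study_model_config(splits), seed=seed, verbose=verbose
    )
    y = res["labels"]
    aucs = {m: roc_auc(ScoredSet(res[m], y))
            for m in ("cp_only", "cxr_only", "combined")}
    combined = ScoredSet(res["combined"], y)
    p_values = {
        m: bootstrap_p_diff(combined, ScoredSet(res[m], y), roc_auc,
                            n_boot=n_boot, seed=seed)
        for m in ("cp_only", "cxr_only")
    }
    return {
        "seed": seed,
        "aucs": aucs,
        "p_values": p_values,
        "oracles": {
            "image": oracle_auc(truth, "image"),
            "clinical": oracle_auc(truth, "clinical"),
            "combined": oracle_auc(truth, "combined",
                                   cohort_cfg.beta_img, cohort_cfg.beta_cp),
        },
        "scores": {m: res[m] for m in ("cp_only", "cxr_only", "combined")},
        "models": res["models"],
        "splits": splits,
        "truth": truth,
    }
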