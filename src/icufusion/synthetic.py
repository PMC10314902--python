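"""Synthetic paired cohort: radiograph-like images, 48-h clinical series, labels.

Each patient carries two independent standard-normal latent severities,
``u_img`` (visible in the image) and ``u_cp`` (visible in the clinical
series); the in-hospital death label is Bernoulli with

    p_death = sigmoid(beta0 + beta_img * u_img + beta_cp * u_cp)

so the unimodal-vs-combined AUROC ordering is tunable through the effect
sizes, and ``oracle_auc`` gives the latent-score ceiling any trained model
can be compared against.

Images are a smooth lung-field-like background plus a Gaussian opacity
whose contrast is strictly monotone in ``u_img``, with pixel noise.
Clinical series use the schema's population means/SDs as AR(1) baselines;
a designated subset of items (heart rate, respiratory rate, oxygen
saturation, GCS sub-scores) shifts monotonically with ``u_cp``.  Hourly
values are dropped at a per-item missing rate, and the items flagged
all-missing are never observed — exercising the 17 -> 2-dropped -> 15
schema reduction downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.signal import lfilter
from scipy.special import expit, logit, ndtr

from .schema import ParameterSchema, default_schema, load_schema
from .tokenizer import ClinicalEventStream, ClinicalMatrix

__all__ = [
    "CohortConfig",
    "LatentTruth",
    "SyntheticSample",
    "generate_cohort",
    "oracle_auc",
    "write_fixture",
    "load_fixture",
]

SIGNAL_DIRECTIONS = {
    # severity raises heart and respiratory rates, lowers oxygen saturation
    "heart rate": +1.0,
    "respiratory rate": +1.0,
    "oxygen saturation": -1.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the real-cohort structure: ~16% in-hospital death
    prevalence, two clinical items that are missing for every stay, one
    radiograph per patient, and both modalities carrying signal.
    """

    n_patients: int = 2000
    image_size: int = 64
    T: int = 48
    beta_img: float = 1.4
    beta_cp: float = 1.4
    beta0: float = float(logit(0.16))
    missing_rate: float = 0.30
    signal_effect: float = 0.9  # SD shift of a signal item per unit u_cp
    items_all_missing: tuple[str, ...] = (
        "capillary refill rate",
        "glasgow coma scale total",
    )
    radiographs_per_patient: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.radiographs_per_patient < 1:
            raise ValueError("radiographs_per_patient must be >= 1")


@dataclass
class LatentTruth:
    """Per-patient latent severities and the implied death probability."""

    patient_ids: list[str]
    u_img: np.ndarray
    u_cp: np.ndarray
    p_death: np.ndarray
    labels: np.ndarray


@dataclass
class SyntheticSample:
    """One paired record before preprocessing: raw image + gridded events."""

    patient_id: str
    stay_id: str
    image_id: str
    image: np.ndarray  # (S, S) grayscale in [0, 1]
    item_names: list[str]
    matrix_values: np.ndarray  # (K, T) with NaN for unobserved
    matrix_observed: np.ndarray
    label: int

    def to_stream(self) -> ClinicalEventStream:
        """Materialise one event per observed cell, timestamped mid-bin."""
        events = []
        ks, ts = np.nonzero(self.matrix_observed)
        for k, t in zip(ks.tolist(), ts.tolist()):
            events.append(
                (self.item_names[k], t + 0.5, float(self.matrix_values[k, t]))
            )
        return ClinicalEventStream(stay_id=self.stay_id, events=events)


def _make_image(rng: np.random.Generator, size: int, u_img: float) -> np.ndarray:
    """Smooth background + central opacity with contrast monotone in u_img."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    background = 0.30 + 0.12 * np.exp(-((yy - 0.5) ** 2) / 0.35)  # mediastinal band
    coarse = rng.normal(0.0, 1.0, size=(4, 4))
    field = np.kron(coarse, np.ones((size // 4, size // 4)))
    # cheap smoothing of the coarse field
    field = 0.25 * (
        field
        + np.roll(field, size // 8, axis=0)
        + np.roll(field, size // 8, axis=1)
        + np.roll(np.roll(field, size // 8, axis=0), size // 8, axis=1)
    )
    background = background + 0.04 * field
    cy = 0.5 + 0.08 * rng.normal()
    cx = 0.5 + 0.08 * rng.normal()
    sigma = 0.16 + 0.02 * rng.normal()
    blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    amplitude = 0.10 + 0.30 * ndtr(u_img)  # strictly increasing in u_img
    img = background + amplitude * blob + rng.normal(0.0, 0.03, size=(size, size))
    return np.clip(img, 0.0, 1.0)


def _clinical_grids(
    rng: np.random.Generator, schema: ParameterSchema, cfg: CohortConfig,
    u_cp: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(n, K, T) values and observed mask for all stays, vectorised per item."""
    n = u_cp.shape[0]
    K, T = schema.K, cfg.T
    values = np.full((n, K, T), np.nan)
    observed = np.zeros((n, K, T), dtype=bool)
    for k, item in enumerate(schema.items):
        if item.name in cfg.items_all_missing:
            continue
        if item.kind == "continuous":
            mean, sd = item.mean, item.sd
            if mean is None or sd is None:
                mean, sd = float(item.default), 1.0
            center = mean + sd * 0.4 * rng.normal(size=n)
            direction = SIGNAL_DIRECTIONS.get(item.name, 0.0)
            center = center + direction * cfg.signal_effect * sd * u_cp
            # AR(1) around each stay's center: x_t = 0.8 x_{t-1} + noise
            noise = 0.3 * sd * rng.normal(size=(n, T))
            noise[:, 0] = 0.5 * sd * rng.normal(size=n)
            ar = lfilter([1.0], [1.0, -0.8], noise, axis=1)
            series = center[:, None] + ar
            if item.name == "fraction inspired oxygen":
                series = np.clip(series, 0.21, 1.0)
            if item.name == "oxygen saturation":
                series = np.clip(series, 50.0, 100.0)
        else:
            # GCS-like ordinal: severity pushes the score below its healthy default
            cats = np.array([float(c) for c in item.categories])
            latent = float(item.default) - np.maximum(
                0.0, 1.2 * u_cp[:, None] + 0.5 * rng.normal(size=(n, T))
            )
            series = np.clip(np.round(latent), cats.min(), cats.max())
        keep = rng.random((n, T)) >= cfg.missing_rate
        values[:, k, :][keep] = series[keep]
        observed[:, k, :] = keep
    return values, observed


def generate_cohort(
    cfg: CohortConfig, schema: ParameterSchema | None = None
) -> tuple[list[SyntheticSample], LatentTruth]:
    """Draw a full paired cohort, bitwise-reproducible from cfg.seed."""
    schema = schema if schema is not None else default_schema()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    u_img = rng.normal(size=n)
    u_cp = rng.normal(size=n)
    p_death = expit(cfg.beta0 + cfg.beta_img * u_img + cfg.beta_cp * u_cp)
    labels = (rng.random(n) < p_death).astype(int)
    patient_ids = [f"p{i:05d}" for i in range(n)]
    all_values, all_observed = _clinical_grids(rng, schema, cfg, u_cp)
    samples: list[SyntheticSample] = []
    names = schema.names
    for i, pid in enumerate(patient_ids):
        values, observed = all_values[i], all_observed[i]
        for r in range(cfg.radiographs_per_patient):
            img = _make_image(rng, cfg.image_size, u_img[i])
            samples.append(
                SyntheticSample(
                    patient_id=pid,
                    stay_id=f"{pid}s0",
                    image_id=f"{pid}_{r}",
                    image=img,
                    item_names=names,
                    matrix_values=values,
                    matrix_observed=observed,
                    label=int(labels[i]),
                )
            )
    truth = LatentTruth(patient_ids, u_img, u_cp, p_death, labels)
    return samples, truth


def oracle_auc(truth: LatentTruth, modality: str = "combined",
               beta_img: float | None = None, beta_cp: float | None = None) -> float:
    """AUROC of the true latent score against the drawn labels.

    ``modality`` selects u_img, u_cp, or their beta-weighted sum — the
    ceiling a model restricted to that modality could approach.
    """
    from .evaluation import ScoredSet, roc_auc

    if modality == "image":
        score = truth.u_img
    elif modality == "clinical":
        score = truth.u_cp
    elif modality == "combined":
        bi = 1.0 if beta_img is None else beta_img
        bc = 1.0 if beta_cp is None else beta_cp
        score = bi * truth.u_img + bc * truth.u_cp
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return roc_auc(ScoredSet(score, truth.labels))


# ------------------------------------------------------------------ fixtures

def write_fixture(
    samples: list[SyntheticSample],
    directory: str | Path,
    cfg: CohortConfig,
    schema: ParameterSchema | None = None,
) -> Path:
    """Write events.csv, labels.csv, schema.yaml, PNG images and a manifest."""
    schema = schema if schema is not None else default_schema()
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    seen_stays = set()
    for s in samples:
        if s.stay_id not in seen_stays:
            seen_stays.add(s.stay_id)
            for name, t, v in s.to_stream().events:
                rows.append((s.stay_id, name, t, v))
    pd.DataFrame(rows, columns=["stay_id", "item_name", "time_h", "value"]).to_csv(
        directory / "events.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "stay_id": s.stay_id,
                "image_id": s.image_id,
                "label": s.label,
            }
            for s in samples
        ]
    ).to_csv(directory / "labels.csv", index=False)
    schema.save(directory / "schema.yaml")
    for s in samples:
        arr = np.clip(s.image * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(directory / "images" / f"{s.image_id}.png")
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
        "n_samples": len(samples),
        "schema_hash": schema.content_hash(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory / "manifest.json"


def load_fixture(directory: str | Path):
    """Reload a written fixture: (samples-as-dicts, schema, manifest)."""
    from .tokenizer import streams_from_csv

    directory = Path(directory)
    schema = load_schema(directory / "schema.yaml")
    manifest = json.loads((directory / "manifest.json").read_text())
    streams = streams_from_csv(directory / "events.csv")
    labels = pd.read_csv(
        directory / "labels.csv",
        dtype={"patient_id": str, "stay_id": str, "image_id": str},
    )
    records = []
    for _, row in labels.iterrows():
        img = np.asarray(
            Image.open(directory / "images" / f"{row.image_id}.png"), dtype=np.float64
        ) / 255.0
        records.append(
            {
                "patient_id": row.patient_id,
                "stay_id": row.stay_id,
                "image_id": row.image_id,
                "image": img,
                "stream": streams.get(row.stay_id, ClinicalEventStream(row.stay_id, [])),
                "label": int(row.label),
            }
        )
    return records, schema, manifest
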