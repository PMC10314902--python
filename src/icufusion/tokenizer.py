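"""Clinical time-series tokenisation: hourly binning, imputation, encoding.

A per-stay event stream (item, hours-since-admission, value) becomes

1. a K x T grid of last-observation-per-hour values with an observed mask
   (:func:`bin_events`),
2. a fully observed grid via forward fill, falling back to the schema's
   pre-specified impute default before the first observation
   (:func:`impute`),
3. an F x T feature matrix with categoricals one-hot expanded and
   continuous values standardised with training-split statistics
   (:func:`encode`), and
4. M = T latent tokens of width D via a learnable linear projection of
   each hourly feature vector (:func:`project_tokens`).

T defaults to 48: the first 48 hours of the ICU stay, one bin per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Linear, Tensor
from .schema import ParameterSchema
from .types import TokenBlock

__all__ = [
    "ClinicalEventStream",
    "ClinicalMatrix",
    "FeatureMatrix",
    "FeatureScaler",
    "bin_events",
    "impute",
    "encode",
    "project_tokens",
    "streams_from_csv",
    "streams_to_csv",
]

T_DEFAULT = 48


@dataclass
class ClinicalEventStream:
    """Raw charted events for one ICU stay, unsorted, in hours since admission."""

    stay_id: str
    events: list[tuple[str, float, float]] = field(default_factory=list)

    def validate(self, schema: ParameterSchema) -> None:
        for name, t, _ in self.events:
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"stay {self.stay_id}: bad event time {t!r} for {name}")
            if name not in schema:
                raise KeyError(f"stay {self.stay_id}: unknown item {name!r}")


@dataclass
class ClinicalMatrix:
    """K x T value grid plus observed mask; unobserved cells hold NaN."""

    values: np.ndarray  # (K, T) float
    observed: np.ndarray  # (K, T) bool
    item_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != self.observed.shape:
            raise ValueError("values/observed shape mismatch")
        if self.values.shape[0] != len(self.item_names):
            raise ValueError("row count does not match item_names")
        # unobserved cells must be the NaN sentinel, never a silent number
        if np.isfinite(self.values[~self.observed]).any():
            raise ValueError("unobserved cell holds a finite value")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """Fully encoded F x T grid ready for the linear token projection."""

    features: np.ndarray  # (F, T) float, no missing entries
    feature_names: list[str]
    source_item: list[str]  # parallel to feature_names

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if not np.isfinite(self.features).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.features.shape[0] != len(self.feature_names) != len(self.source_item):
            raise ValueError("feature naming out of sync with matrix")

    @property
    def F(self) -> int:
        return self.features.shape[0]

    @property
    def T(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.features.copy(), list(self.feature_names), list(self.source_item)
        )


def bin_events(
    stream: ClinicalEventStream, schema: ParameterSchema, T: int = T_DEFAULT
) -> ClinicalMatrix:
    """Grid events onto hourly bins [t, t+1); the last event in a bin wins.

    Events at or after T hours are discarded.  Ordering within a bin follows
    event time; equal-time events resolve to the one latest in the input.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    stream.validate(schema)
    K = schema.K
    values = np.full((K, T), np.nan)
    observed = np.zeros((K, T), dtype=bool)
    last_time = np.full((K, T), -np.inf)
    for order, (name, t_h, raw) in enumerate(stream.events):
        if t_h >= T:
            continue
        k = schema.index(name)
        item = schema[name]
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValueError(
                f"stay {stream.stay_id}: non-numeric value {raw!r} "
                f"for {name} at {t_h} h"
            ) from None
        if item.kind == "categorical" and val not in [float(c) for c in item.categories]:
            raise ValueError(
                f"stay {stream.stay_id}: value {raw!r} for categorical {name} "
                f"at {t_h} h not among {item.categories}"
            )
        b = int(t_h)
        # stable last-value-wins: later time, or same time but later in input
        key = t_h + order * 1e-12
        if key >= last_time[k, b]:
            last_time[k, b] = key
            values[k, b] = val
            observed[k, b] = True
    return ClinicalMatrix(values, observed, schema.names)


def impute(matrix: ClinicalMatrix, schema: ParameterSchema) -> ClinicalMatrix:
    """Forward-fill each item along time; pre-first-observation bins take the
    schema default.  Fill never propagates backwards.  The returned grid is
    fully observed; keep the input's mask if downstream needs raw missingness.
    """
    if matrix.item_names != schema.names:
        raise ValueError("matrix items do not match schema")
    for item in schema.items:
        if item.default is None:
            raise ValueError(f"{item.name}: no impute default available")
    defaults = np.array([float(it.default) for it in schema.items])
    T = matrix.T
    # index of the most recent observed bin at or before t (-1 if none yet)
    idx = np.where(matrix.observed, np.arange(T)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    rows = np.arange(matrix.K)[:, None]
    values = np.where(
        idx >= 0,
        matrix.values[rows, np.maximum(idx, 0)],
        defaults[:, None],
    )
    return ClinicalMatrix(values, np.ones_like(matrix.observed), list(matrix.item_names))


@dataclass
class FeatureScaler:
    """Per-feature (center, scale) for the encoded matrix.

    Continuous features are standardised; one-hot indicator features pass
    through (center 0, scale 1).  Fit on the training split only.  Features
    that are constant in the fit data get scale 1 so they encode to zero
    rather than blowing up.
    """

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def identity(cls, schema: ParameterSchema) -> "FeatureScaler":
        F = schema.n_features
        return cls(np.zeros(F), np.ones(F))

    @classmethod
    def fit(cls, matrices: list[ClinicalMatrix], schema: ParameterSchema) -> "FeatureScaler":
        raw = [_expand(m, schema) for m in matrices]
        stacked = np.concatenate([r for r in raw], axis=1)  # (F, n*T)
        center = stacked.mean(axis=1)
        scale = stacked.std(axis=1)
        names, source = schema.feature_layout()
        is_onehot = np.array(["=" in n for n in names])
        center[is_onehot] = 0.0
        scale[is_onehot] = 1.0
        scale[scale < 1e-8] = 1.0
        return cls(center, scale)


def _expand(matrix: ClinicalMatrix, schema: ParameterSchema) -> np.ndarray:
    """Raw (unscaled) F x T expansion: continuous rows + one-hot groups."""
    if not matrix.observed.all():
        raise ValueError("encode requires an imputed (fully observed) matrix")
    rows = []
    for k, item in enumerate(schema.items):
        vals = matrix.values[k]
        if item.kind == "continuous":
            rows.append(vals[None, :])
        else:
            cats = np.array([float(c) for c in item.categories])
            bad = ~np.isin(vals, cats)
            if bad.any():
                t = int(np.argmax(bad))
                raise ValueError(
                    f"{item.name}: value {vals[t]!r} at bin {t} not among categories"
                )
            onehot = (vals[None, :] == cats[:, None]).astype(np.float64)
            rows.append(onehot)
    return np.concatenate(rows, axis=0)


def encode(
    matrix: ClinicalMatrix, schema: ParameterSchema, scaler: FeatureScaler
) -> FeatureMatrix:
    """One-hot categoricals, standardise continuous values, no missing cells."""
    raw = _expand(matrix, schema)
    names, source = schema.feature_layout()
    if scaler.center.shape[0] != raw.shape[0]:
        raise ValueError(
            f"scaler fitted for {scaler.center.shape[0]} features, matrix has {raw.shape[0]}"
        )
    feats = (raw - scaler.center[:, None]) / scaler.scale[:, None]
    return FeatureMatrix(feats, names, source)


def project_tokens(fm: FeatureMatrix, projection: Linear) -> TokenBlock:
    """M = T clinical tokens: token t is the linear image of hour t's features."""
    if projection.in_features != fm.F:
        raise ValueError(
            f"projection expects {projection.in_features} features, matrix has {fm.F}"
        )
    tokens = projection(Tensor(fm.features.T))  # (T, D)
    return TokenBlock(tokens=tokens, modality="clinical")


# ----------------------------------------------------------------- event CSV I/O

def streams_from_csv(path: str | Path) -> dict[str, ClinicalEventStream]:
    """Read `stay_id,item_name,time_h,value` rows into per-stay event streams."""
    df = pd.read_csv(path, dtype={"stay_id": str, "item_name": str})
    required = {"stay_id", "item_name", "time_h", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    streams: dict[str, ClinicalEventStream] = {}
    for stay_id, group in df.groupby("stay_id", sort=True):
        events = list(
            zip(group["item_name"], group["time_h"].astype(float), group["value"])
        )
        streams[stay_id] = ClinicalEventStream(stay_id=stay_id, events=events)
    return streams


def streams_to_csv(streams: dict[str, ClinicalEventStream], path: str | Path) -> None:
    rows = [
        (s.stay_id, name, t, v)
        for s in streams.values()
        for name, t, v in s.events
    ]
    pd.DataFrame(rows, columns=["stay_id", "item_name", "time_h", "value"]).to_csv(
        path, index=False
    )
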