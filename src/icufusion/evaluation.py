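"""Metrics, bootstrap uncertainty and the missing-parameter stress test.

AUROC is computed as the Mann-Whitney probability (ties count one half),
AUPRC as average precision, and the operating point by Youden's criterion:
the observed score maximising sensitivity + specificity, predicting
positive at score >= threshold.  Confidence intervals are percentile
bootstrap over sample-level redraws (10,000 by default); model comparisons
use a paired bootstrap of the metric difference, with DeLong's test
available as an analytic cross-check for AUROC.

The robustness experiment rescores the full test set with k randomly
chosen clinical parameters masked to zero (images always provided),
repeated over many random subsets per k, recording AUROC and the PPV at
the per-run Youden threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score

from .model import MultimodalTransformer, mask_feature_batch

__all__ = [
    "ScoredSet",
    "EvalReport",
    "RobustnessResult",
    "roc_auc",
    "pr_auc",
    "youden_threshold",
    "bootstrap_ci",
    "bootstrap_p_diff",
    "delong_p",
    "evaluate",
    "roc_curve_points",
    "pr_curve_points",
    "robustness_experiment",
]


@dataclass
class ScoredSet:
    """Per-sample scores and binary labels (1 = died in hospital)."""

    scores: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be parallel 1-d arrays")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def both_classes(self) -> bool:
        return 0 < self.labels.sum() < self.n


def _require_both_classes(s: ScoredSet, op: str) -> None:
    if not s.both_classes():
        raise ValueError(f"{op} needs both classes present")


def roc_auc(s: ScoredSet) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    _require_both_classes(s, "roc_auc")
    pos = s.labels == 1
    n_pos = int(pos.sum())
    n_neg = s.n - n_pos
    ranks = rankdata(s.scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(s: ScoredSet) -> float:
    """Average-precision area under the precision-recall curve."""
    if s.labels.sum() == 0:
        raise ValueError("pr_auc needs at least one positive")
    return float(average_precision_score(s.labels, s.scores))


def youden_threshold(s: ScoredSet) -> tuple[float, float, float, float]:
    """Observed-score threshold maximising sensitivity + specificity.

    Positive prediction at score >= threshold; ties in the criterion break
    toward the lower threshold (higher sensitivity).  Returns
    (threshold, sensitivity, specificity, ppv).
    """
    _require_both_classes(s, "youden_threshold")
    order = np.argsort(s.scores, kind="stable")
    scores = s.scores[order]
    labels = s.labels[order]
    uniq, first_idx = np.unique(scores, return_index=True)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    # predicting positive at >= uniq[j] excludes samples ranked before first_idx[j]
    cum_pos = np.concatenate([[0], np.cumsum(labels)])
    cum_neg = np.concatenate([[0], np.cumsum(1 - labels)])
    tp = n_pos - cum_pos[first_idx]
    fp = n_neg - cum_neg[first_idx]
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec
    best = int(np.argmin(-j))  # argmin of negated: first (lowest threshold) maximum
    ppv = tp[best] / (tp[best] + fp[best]) if tp[best] + fp[best] > 0 else 0.0
    return float(uniq[best]), float(sens[best]), float(spec[best]), float(ppv)


def _resample_indices(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """One bootstrap redraw, redrawn until both classes are present."""
    n = labels.size
    while True:
        idx = rng.integers(0, n, size=n)
        ssum = labels[idx].sum()
        if 0 < ssum < n:
            return idx


def bootstrap_ci(
    s: ScoredSet, metric, n_boot: int = 10_000, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile 2.5/97.5 interval of `metric` over sample-level redraws."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = metric(s)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = _resample_indices(rng, s.labels)
        stats[b] = metric(ScoredSet(s.scores[idx], s.labels[idx]))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def bootstrap_p_diff(
    sA: ScoredSet, sB: ScoredSet, metric, n_boot: int = 10_000, seed: int = 0
) -> float:
    """Two-sided paired-bootstrap p-value for metric(A) - metric(B).

    The same redraw of sample indices is applied to both score sets, so the
    comparison is paired; the p-value is floored at 1/n_boot.
    """
    if sA.n != sB.n:
        raise ValueError("paired comparison requires equal-length score sets")
    if sA.ids is not None and sB.ids is not None and not np.array_equal(sA.ids, sB.ids):
        raise ValueError("paired comparison requires identical sample ids")
    if not np.array_equal(sA.labels, sB.labels):
        raise ValueError("paired comparison requires identical labels")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = _resample_indices(rng, sA.labels)
        lab = sA.labels[idx]
        deltas[b] = metric(ScoredSet(sA.scores[idx], lab)) - metric(
            ScoredSet(sB.scores[idx], lab)
        )
    p = 2.0 * min((deltas <= 0).mean(), (deltas >= 0).mean())
    return float(min(1.0, max(p, 1.0 / n_boot)))


def delong_p(sA: ScoredSet, sB: ScoredSet) -> float:
    """DeLong's two-sided test for paired AUROC difference (analytic cross-check)."""
    if not np.array_equal(sA.labels, sB.labels):
        raise ValueError("paired comparison requires identical labels")
    labels = sA.labels
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        return 1.0  # variance of the placement values is undefined

    def structural(scores):
        x, y = scores[pos], scores[~pos]
        # placement values via mid-ranks
        all_r = rankdata(np.concatenate([x, y]))
        rx, ry = rankdata(x), rankdata(y)
        v10 = (all_r[:m] - rx) / n  # per-positive
        v01 = 1.0 - (all_r[m:] - ry) / m  # per-negative
        return v10, v01, v10.mean()

    v10a, v01a, auca = structural(sA.scores)
    v10b, v01b, aucb = structural(sB.scores)
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if not np.isfinite(var) or var <= 0:
        return 1.0
    z = (auca - aucb) / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


@dataclass
class EvalReport:
    """Point estimates with bootstrap CIs at the Youden operating point."""

    auroc: tuple[float, float, float]
    auprc: tuple[float, float, float]
    sensitivity: tuple[float, float, float]
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    threshold: float
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        def trip(t):
            return {"point": t[0], "ci_low": t[1], "ci_high": t[2]}

        return {
            "auroc": trip(self.auroc),
            "auprc": trip(self.auprc),
            "sensitivity": trip(self.sensitivity),
            "specificity": trip(self.specificity),
            "ppv": trip(self.ppv),
            "threshold": self.threshold,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def evaluate(
    s: ScoredSet, n_boot: int = 10_000, seed: int = 0, refit_threshold: bool = True
) -> EvalReport:
    """Full metric suite with a single shared set of bootstrap redraws.

    The Youden threshold is refit inside each resample by default; with
    ``refit_threshold=False`` the full-sample threshold is held fixed.
    """
    _require_both_classes(s, "evaluate")
    thr, sens, spec, ppv = youden_threshold(s)
    point = {
        "auroc": roc_auc(s),
        "auprc": pr_auc(s),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
    }
    rng = np.random.default_rng(seed)
    boot = {k: np.empty(n_boot) for k in point}
    for b in range(n_boot):
        idx = _resample_indices(rng, s.labels)
        rs = ScoredSet(s.scores[idx], s.labels[idx])
        boot["auroc"][b] = roc_auc(rs)
        boot["auprc"][b] = pr_auc(rs)
        if refit_threshold:
            _, se, sp, pv = youden_threshold(rs)
        else:
            se, sp, pv = _metrics_at(rs, thr)
        boot["sensitivity"][b] = se
        boot["specificity"][b] = sp
        boot["ppv"][b] = pv

    def ci(name):
        lo, hi = np.percentile(boot[name], [2.5, 97.5])
        return (point[name], float(lo), float(hi))

    return EvalReport(
        auroc=ci("auroc"),
        auprc=ci("auprc"),
        sensitivity=ci("sensitivity"),
        specificity=ci("specificity"),
        ppv=ci("ppv"),
        threshold=thr,
        n=s.n,
        n_boot=n_boot,
        seed=seed,
    )


def _metrics_at(s: ScoredSet, thr: float) -> tuple[float, float, float]:
    pred = s.scores >= thr
    tp = int((pred & (s.labels == 1)).sum())
    fp = int((pred & (s.labels == 0)).sum())
    n_pos = int(s.labels.sum())
    n_neg = s.n - n_pos
    sens = tp / n_pos if n_pos else 0.0
    spec = 1.0 - fp / n_neg if n_neg else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return sens, spec, ppv


def roc_curve_points(s: ScoredSet) -> pd.DataFrame:
    """ROC curve vertices (fpr, tpr, threshold) for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(s.labels, s.scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve_points(s: ScoredSet) -> pd.DataFrame:
    """Precision-recall curve vertices for plotting/export."""
    from sklearn.metrics import precision_recall_curve

    prec, rec, thr = precision_recall_curve(s.labels, s.scores)
    return pd.DataFrame({
        "recall": rec,
        "precision": prec,
        "threshold": np.append(thr, np.nan),
    })


@dataclass
class RobustnessResult:
    """Per-k distributions of AUROC and PPV over random masked subsets."""

    records: pd.DataFrame  # columns: k, rep, auroc, ppv
    seed: int
    reps: int
    item_names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby("k")[["auroc", "ppv"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def mean_auroc(self) -> pd.Series:
        return self.records.groupby("k")["auroc"].mean()


def robustness_experiment(
    model: MultimodalTransformer,
    patches: np.ndarray,
    features: np.ndarray,
    labels: np.ndarray,
    source_item: list[str],
    ks: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14),
    reps: int = 100,
    seed: int = 0,
    batch_size: int = 64,
) -> RobustnessResult:
    """Stress the combined model with k clinical parameters masked at a time.

    For each k and repetition a k-subset of items is drawn uniformly without
    replacement, its encoded feature rows are zeroed across the whole test
    set, and the set is rescored with images always provided.
    """
    items = sorted(set(source_item))
    if max(ks) > len(items):
        raise ValueError(f"cannot mask {max(ks)} of {len(items)} items")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        for rep in range(reps):
            subset = set(rng.choice(items, size=k, replace=False))
            masked = mask_feature_batch(features, source_item, subset)
            scores = model.predict_scores(patches, masked, mode="combined",
                                          batch_size=batch_size)
            s = ScoredSet(scores, labels)
            _, _, _, ppv = youden_threshold(s)
            rows.append({"k": k, "rep": rep, "auroc": roc_auc(s), "ppv": ppv})
    return RobustnessResult(
        records=pd.DataFrame(rows), seed=seed, reps=reps, item_names=items
    )
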