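"""Minimum-distance-to-mean classification and source-subject selection.

The MDM classifier stores one Riemannian mean covariance per class and
assigns a trial to the class with the nearest mean.  Class means are
log-Euclidean means (the study's choice); the classification metric defaults
to log-Euclidean for consistency with the means, with the affine-invariant
metric selectable.

Training-accuracy-based subject selection (TSS) decides *which* source
subjects to pool with the target's own training data: each source is scored
by how well a classifier trained on its data alone classifies the target's
training set; sources are ranked by that score, and the pool size C is the
prefix of the ranking whose pooled classifier scores highest on the target's
training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import SuperCovariance
from .spdcore import dist_ai, expm_sym, mean_ai

__all__ = [
    "MDMModel",
    "TSSResult",
    "train_mdm",
    "classify_mdm",
    "train_then_test",
    "tss",
    "train_transfer_model",
]

logger = logging.getLogger(__name__)

METRICS = ("log_euclidean", "affine_invariant")


@dataclass
class MDMModel:
    """Per-class Riemannian mean covariances plus the classification metric."""

    class_means: dict[int, np.ndarray]
    metric: str = "log_euclidean"
    # Log-domain means, kept for fast log-Euclidean distances.
    class_mean_logs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        dims = {m.shape[0] for m in self.class_means.values()}
        if len(dims) > 1:
            raise ValueError("class means have inconsistent dimensions")

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_means)

    @property
    def dim(self) -> int:
        return next(iter(self.class_means.values())).shape[0]


def train_mdm(
    covs: list[SuperCovariance],
    labels: np.ndarray | None = None,
    metric: str = "log_euclidean",
) -> MDMModel:
    """Fit per-class mean covariances.

    Class means are log-Euclidean means (arithmetic means of matrix logs)
    for the log-Euclidean metric, and Karcher means for the affine-invariant
    metric.  Labels default to the covariances' own labels.
    """
    if labels is None:
        labels = np.array([c.label for c in covs])
        if any(l is None for l in labels):
            raise ValueError("unlabeled covariance in training set")
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(covs):
        raise ValueError("labels length must match covariance count")
    if len(covs) == 0:
        raise ValueError("empty training set")

    class_means: dict[int, np.ndarray] = {}
    class_mean_logs: dict[int, np.ndarray] = {}
    for z in sorted(set(int(l) for l in labels)):
        members = [c for c, l in zip(covs, labels) if int(l) == z]
        if metric == "log_euclidean":
            mean_log = np.mean([c.log() for c in members], axis=0)
            class_mean_logs[z] = mean_log
            class_means[z] = expm_sym(mean_log)
        else:
            class_means[z] = mean_ai([c.matrix for c in members])
    return MDMModel(class_means=class_means, metric=metric, class_mean_logs=class_mean_logs)


def classify_mdm(model: MDMModel, cov: SuperCovariance) -> tuple[int, dict[int, float]]:
    """Assign a covariance to the class with the nearest mean.

    Returns ``(label, distances)``.  Ties break toward the smallest class
    index (and are logged).
    """
    if cov.dim != model.dim:
        raise ValueError(f"covariance dim {cov.dim} != model dim {model.dim}")
    distances: dict[int, float] = {}
    if model.metric == "log_euclidean":
        c_log = cov.log()
        for z in model.classes:
            distances[z] = float(np.linalg.norm(c_log - model.class_mean_logs[z], "fro"))
    else:
        for z in model.classes:
            distances[z] = dist_ai(cov.matrix, model.class_means[z])
    best = min(distances.values())
    winners = [z for z in model.classes if distances[z] == best]
    if len(winners) > 1:
        logger.info("distance tie among classes %s; choosing %d", winners, winners[0])
    return winners[0], distances


def _predict_labels(model: MDMModel, covs: list[SuperCovariance]) -> np.ndarray:
    return np.array([classify_mdm(model, c)[0] for c in covs])


def train_then_test(
    train_covs: list[SuperCovariance],
    train_labels: np.ndarray,
    test_covs: list[SuperCovariance],
    test_labels: np.ndarray,
    metric: str = "log_euclidean",
) -> float:
    """Train an MDM on one set and report accuracy on another."""
    if len(test_covs) == 0:
        raise ValueError("empty test set")
    model = train_mdm(train_covs, train_labels, metric=metric)
    pred = _predict_labels(model, test_covs)
    return float(np.mean(pred == np.asarray(test_labels, dtype=int)))


@dataclass
class TSSResult:
    """Outcome of training-accuracy-based subject selection."""

    per_source_accuracy: dict[str, float]
    ranking: list[str]
    pooled_accuracy: dict[int, float]
    C: int
    selected: list[str]


def tss(
    source_sets: dict[str, tuple[list[SuperCovariance], np.ndarray]],
    target_train: tuple[list[SuperCovariance], np.ndarray],
    metric: str = "log_euclidean",
    include_target_in_pool: bool = True,
) -> TSSResult:
    """Select the source-subject pool by training-set accuracy.

    1. Score each source: MDM trained on that source's covariances alone,
       tested on the target's training covariances.
    2. Rank sources by score, descending (ties stable by source id).
    3. For c = 1..n_sources, pool the top-c sources (plus the target's
       training covariances when ``include_target_in_pool``), retrain, and
       retest on the target's training set.
    4. C = argmax over c (ties toward the smallest c); the selected set is
       the first C of the ranking.
    """
    if not source_sets:
        raise ValueError("need at least one source subject")
    tgt_covs, tgt_labels = target_train
    if len(tgt_covs) == 0:
        raise ValueError("target training set is empty")

    per_source = {
        sid: train_then_test(covs, labels, tgt_covs, tgt_labels, metric=metric)
        for sid, (covs, labels) in sorted(source_sets.items())
    }
    ranking = sorted(per_source, key=lambda sid: (-per_source[sid], sid))

    pooled_accuracy: dict[int, float] = {}
    pool_covs: list[SuperCovariance] = list(tgt_covs) if include_target_in_pool else []
    pool_labels: list[int] = list(np.asarray(tgt_labels, int)) if include_target_in_pool else []
    for c, sid in enumerate(ranking, start=1):
        covs, labels = source_sets[sid]
        pool_covs = pool_covs + list(covs)
        pool_labels = pool_labels + list(np.asarray(labels, int))
        pooled_accuracy[c] = train_then_test(
            pool_covs, np.array(pool_labels), tgt_covs, tgt_labels, metric=metric
        )

    best = max(pooled_accuracy.values())
    C = min(c for c, a in pooled_accuracy.items() if a == best)
    logger.debug("TSS selected C=%d sources (pooled accuracy %.3f)", C, best)
    return TSSResult(
        per_source_accuracy=per_source,
        ranking=ranking,
        pooled_accuracy=pooled_accuracy,
        C=C,
        selected=ranking[:C],
    )


def train_transfer_model(
    selected_sources: dict[str, tuple[list[SuperCovariance], np.ndarray]],
    target_train: tuple[list[SuperCovariance], np.ndarray],
    metric: str = "log_euclidean",
) -> MDMModel:
    """Train the final MDM on pooled source + target training covariances.

    Every covariance weighs equally; with an empty selection this reduces to
    the subject-specific model.
    """
    covs, labels = target_train
    pool_covs = list(covs)
    pool_labels = list(np.asarray(labels, int))
    for sid in sorted(selected_sources):
        s_covs, s_labels = selected_sources[sid]
        pool_covs += list(s_covs)
        pool_labels += list(np.asarray(s_labels, int))
    return train_mdm(pool_covs, np.array(pool_labels), metric=metric)
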