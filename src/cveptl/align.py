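"""Log-Euclidean data alignment (LEDA).

Different subjects' EEG occupies different linear channel frames; pooling
their trials naively shifts the pooled covariance distribution and degrades
transfer.  LEDA whitens each subject's trials by the inverse square root of
the log-Euclidean mean of their trial covariances,

    M_ref = P̄_LE^{-1/2},     X' = M_ref · X,

either globally (*unsupervised*, used for the target subject's unlabeled
test trials) or with one reference per class (*supervised*, used for
labeled training/source trials).  Because congruence by a common invertible
matrix leaves affine-invariant distances unchanged, alignment preserves the
relative geometry within each subject while moving every subject toward a
common (whitened) reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spdcore import invsqrt, mean_le, scm

__all__ = ["AlignmentModel", "fit_unsupervised", "fit_supervised", "apply"]


@dataclass(frozen=True)
class AlignmentModel:
    """Fitted LEDA references.

    ``mode`` is ``"unsupervised"`` (one global reference) or
    ``"supervised"`` (one reference per class).  References are symmetric
    positive definite, equal to the inverse square root of the log-Euclidean
    mean of the (unshrunk) trial covariances they were fitted on.
    """

    mode: str
    references: dict[int | None, np.ndarray]

    def reference(self, label: int | None = None) -> np.ndarray:
        if self.mode == "unsupervised":
            return self.references[None]
        if label is None:
            raise ValueError("supervised alignment requires a class label")
        if label not in self.references:
            raise ValueError(f"no alignment reference for class {label}")
        return self.references[label]


def fit_unsupervised(trials: np.ndarray) -> AlignmentModel:
    """Global LEDA reference from all trials, regardless of class.

    ``trials`` is trials × channels × samples.
    """
    x = np.asarray(trials, dtype=float)
    if x.ndim != 3 or x.shape[0] == 0:
        raise ValueError("need a nonempty trials x channels x samples array")
    covs = [scm(t) for t in x]
    ref = invsqrt(mean_le(covs))
    return AlignmentModel(mode="unsupervised", references={None: ref})


def fit_supervised(trials: np.ndarray, labels: np.ndarray) -> AlignmentModel:
    """Per-class LEDA references from labeled trials."""
    x = np.asarray(trials, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if x.ndim != 3 or x.shape[0] == 0:
        raise ValueError("need a nonempty trials x channels x samples array")
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match trial count")
    references: dict[int | None, np.ndarray] = {}
    for z in np.unique(labels):
        covs = [scm(t) for t in x[labels == z]]
        references[int(z)] = invsqrt(mean_le(covs))
    return AlignmentModel(mode="supervised", references=references)


def apply(
    model: AlignmentModel, trial: np.ndarray, label: int | None = None
) -> np.ndarray:
    """Align one trial: left-multiply by the (class-specific) reference.

    The aligned trial's covariance is ``M_ref · P · M_ref^T``.
    """
    ref = model.reference(label)
    trial = np.asarray(trial, dtype=float)
    if trial.shape[0] != ref.shape[0]:
        raise ValueError(
            f"trial has {trial.shape[0]} rows, reference is {ref.shape[0]}-dim"
        )
    return ref @ trial


def apply_set(
    model: AlignmentModel, trials: np.ndarray, labels: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized :func:`apply` over a stack of trials."""
    x = np.asarray(trials, dtype=float)
    if model.mode == "unsupervised":
        ref = model.reference()
        return np.einsum("ij,njt->nit", ref, x)
    if labels is None:
        raise ValueError("supervised alignment requires labels")
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = apply(model, x[i], int(labels[i]))
    return out
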