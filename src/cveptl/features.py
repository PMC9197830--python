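"""Super-trial construction and (shrunk) super-trial covariance estimation.

The plain covariance of a c-VEP trial carries no class information: every
target plays the same code at a different lag, and a circular lag leaves
second-order spatial statistics unchanged.  The super-trial fixes this by
stacking all class templates on top of the trial,

    X'_z = [X̄_1; X̄_2; …; X̄_Z; X_z]   ∈ R^{Nc(Z+1) × Nt},

so the covariance of the stack contains trial–template cross-covariance
blocks: the block belonging to the true class dominates, and Riemannian
nearest-mean classification becomes possible on lag-coded classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TemplateSet
from .spdcore import ShrinkageConfig, scm, shrink

__all__ = ["SuperTrial", "SuperCovariance", "build_supertrial", "supertrial_cov"]


@dataclass(frozen=True)
class SuperTrial:
    """Templates-plus-trial stack (``Nc(Z+1)`` × ``Nt``)."""

    values: np.ndarray
    n_classes: int
    n_channels: int
    label: int | None = None
    subject_id: str | None = None


@dataclass(frozen=True)
class SuperCovariance:
    """Shrunk covariance of a super-trial, the pipeline's feature object."""

    matrix: np.ndarray
    label: int | None = None
    subject_id: str | None = None
    shrinkage: str = "none"

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def log(self) -> np.ndarray:
        """Matrix logarithm of the covariance, computed once and cached.

        Log-Euclidean means and distances are linear in the log domain, so
        classifiers and subject-selection loops reuse this heavily.
        """
        cached = getattr(self, "_log_cache", None)
        if cached is None:
            from .spdcore import logm_spd

            cached = logm_spd(self.matrix)
            object.__setattr__(self, "_log_cache", cached)
        return cached


def build_supertrial(
    templates: TemplateSet,
    trial: np.ndarray,
    label: int | None = None,
    subject_id: str | None = None,
) -> SuperTrial:
    """Stack the class templates above a trial, templates in class order.

    ``label`` may be None for an unlabeled test trial — the stack is built
    the same way, with the trial in the last row block.
    """
    trial = np.asarray(trial, dtype=float)
    Z, nc, nt = templates.templates.shape
    if trial.shape != (nc, nt):
        raise ValueError(
            f"trial shape {trial.shape} does not match templates ({nc}, {nt})"
        )
    stack = np.concatenate([templates.templates.reshape(Z * nc, nt), trial], axis=0)
    return SuperTrial(
        values=stack, n_classes=Z, n_channels=nc, label=label, subject_id=subject_id
    )


def supertrial_cov(
    st: SuperTrial, config: ShrinkageConfig = ShrinkageConfig()
) -> SuperCovariance:
    """SCM of the super-trial followed by shrinkage.

    The analytic shrinkage intensity (when ``config.lam`` is None) is
    estimated from the super-trial samples themselves.
    """
    P = scm(st.values)
    X = st.values - st.values.mean(axis=1, keepdims=True)
    P_sh = shrink(P, config, data=X)
    return SuperCovariance(
        matrix=P_sh, label=st.label, subject_id=st.subject_id, shrinkage=config.method
    )
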