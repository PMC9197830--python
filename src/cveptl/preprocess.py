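"""Band-pass filtering, epoching, trial shifting, and template averaging.

Trial shifting is the trick that makes single-reference-target training
possible in a c-VEP interface: because every target plays the *same* code at
a different circular lag, EEG recorded while fixating the reference target
can be rotated in time to synthesize training trials for every other target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .codes import CodeBook

__all__ = ["FilterSpec", "TemplateSet", "bandpass", "epoch", "shift_trials", "make_templates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``order`` is the overall filter order (a band-pass design doubles the
    low-pass prototype order, so order 8 uses a 4th-order prototype).
    ``zero_phase`` selects forward–backward filtering (no group delay,
    standard for offline analysis); the causal mode is retained for online
    use.
    """

    low_hz: float = 2.0
    high_hz: float = 30.0
    order: int = 8
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be a positive even integer")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        return scipy.signal.butter(
            self.order // 2,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )


def bandpass(trials: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Band-pass filter along the last (time) axis.

    Accepts a single trial (channels × samples) or a stack of trials
    (... × channels × samples); shape is preserved.
    """
    x = np.asarray(trials, dtype=float)
    nt = x.shape[-1]
    if nt < 3 * spec.order:
        raise ValueError(
            f"trial too short for filtering: {nt} samples < 3x order {spec.order}"
        )
    sos = spec.sos(fs)
    if spec.zero_phase:
        return scipy.signal.sosfiltfilt(sos, x, axis=-1)
    return scipy.signal.sosfilt(sos, x, axis=-1)


def epoch(continuous: np.ndarray, onsets: np.ndarray, n_samples: int) -> np.ndarray:
    """Cut a continuous recording (channels × time) into trials.

    Returns trials × channels × n_samples.  Overlapping onsets are allowed;
    out-of-bounds windows raise with the offending onset named.
    """
    x = np.asarray(continuous)
    if x.ndim != 2:
        raise ValueError("continuous data must be channels x time")
    onsets = np.asarray(onsets, dtype=int)
    total = x.shape[1]
    bad = [int(o) for o in onsets if o < 0 or o + n_samples > total]
    if bad:
        raise ValueError(
            f"onsets {bad} out of bounds for {total} samples with window {n_samples}"
        )
    return np.stack([x[:, o : o + n_samples] for o in onsets])


def samples_per_target_step(codebook: CodeBook, fs: float) -> float:
    """Samples corresponding to one inter-target lag (τ_s bits) at ``fs``."""
    return fs * codebook.lag_bits / codebook.bit_rate


def shift_trials(
    reference_trials: np.ndarray,
    codebook: CodeBook,
    target_z: int,
    fs: float,
    tolerance: float = 1e-9,
) -> np.ndarray:
    """Rotate reference-target trials to synthesize target ``z`` trials.

    The rotation is circular along time by ``(z − reference) · τ_s`` bits
    converted to samples (right rotation = delay, matching the codebook's
    shift direction).  Trials must be whole stimulus cycles.  Non-integer
    sample shifts are rounded to the nearest sample with a logged warning
    (e.g. at 1000 Hz a 4-bit step is 66.67 samples); at the package-default
    600 Hz every step is an exact 40 samples.
    """
    x = np.asarray(reference_trials)
    if not 0 <= target_z < codebook.n_targets:
        raise ValueError(f"target {target_z} out of range")
    delta_bits = (target_z - codebook.reference_target) * codebook.lag_bits
    shift = fs * delta_bits / codebook.bit_rate
    rounded = round(shift)
    if abs(shift - rounded) > tolerance:
        logger.warning(
            "non-integer sample shift %.4f for target %d rounded to %d "
            "(residual %.4f samples)",
            shift,
            target_z,
            rounded,
            shift - rounded,
        )
    if rounded == 0:
        return x.copy()
    return np.roll(x, rounded, axis=-1)


@dataclass(frozen=True)
class TemplateSet:
    """Per-class average responses X̄_1..X̄_Z (classes × channels × samples)."""

    templates: np.ndarray
    n_trials_used: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


def make_templates(trials: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> TemplateSet:
    """Arithmetic per-class mean of trials (trials × channels × samples).

    Every class in ``0..n_classes−1`` must have at least one trial; a missing
    class raises naming it.
    """
    x = np.asarray(trials, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if x.ndim != 3:
        raise ValueError("trials must be trials x channels x samples")
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match trial count")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    templates = np.empty((n_classes,) + x.shape[1:], dtype=float)
    counts = np.zeros(n_classes, dtype=int)
    for z in range(n_classes):
        mask = labels == z
        counts[z] = mask.sum()
        if counts[z] == 0:
            raise ValueError(f"no trials for class {z}; cannot build its template")
        templates[z] = x[mask].mean(axis=0)
    return TemplateSet(templates=templates, n_trials_used=counts)
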