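"""Maximum-length sequences and circular-shift codebooks for c-VEP stimulation.

In a code-modulated VEP (c-VEP) interface every stimulus flickers with the
*same* pseudorandom binary sequence, delayed by a target-specific circular
lag.  Maximum-length sequences (m-sequences) are the standard choice because
their circular autocorrelation is two-valued (``L`` at lag 0, ``-1``
elsewhere), so responses to different lags are maximally distinguishable.

This module generates m-sequences with a Fibonacci linear-feedback shift
register (LFSR), verifies the defining m-sequence properties at runtime, and
assembles the per-target codebook (one lagged copy of the base code per
stimulus target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BinaryCode",
    "CodeBook",
    "generate_msequence",
    "shift_code",
    "build_codebook",
    "default_codebook",
    "DEFAULT_TAPS",
]

#: Feedback taps of the default degree-6 primitive polynomial
#: x^6 + x^5 + 1 (stage numbers, 1-based).  Any primitive degree-6
#: polynomial yields a 63-bit sequence with identical balance and
#: autocorrelation properties; primitivity is re-verified at runtime by
#: measuring the LFSR period.
DEFAULT_TAPS: tuple[int, ...] = (6, 5)


@dataclass(frozen=True)
class BinaryCode:
    """A periodic binary modulation sequence.

    Parameters
    ----------
    bits
        The 0/1 sequence defining one period of the flicker pattern.
    bit_rate
        Presentation rate in bits/second (the monitor refresh rate).
    """

    bits: tuple[int, ...]
    bit_rate: float = 60.0

    def __post_init__(self) -> None:
        if len(self.bits) < 3:
            raise ValueError(f"code length must be >= 3, got {len(self.bits)}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("code bits must be 0 or 1")
        if self.bit_rate <= 0:
            raise ValueError("bit_rate must be positive")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def period_s(self) -> float:
        """Seconds per full cycle of the code."""
        return len(self.bits) / self.bit_rate

    def bipolar(self) -> np.ndarray:
        """Return the sequence mapped to ±1 (1 → +1, 0 → −1)."""
        return 2.0 * np.asarray(self.bits, dtype=float) - 1.0

    def autocorrelation(self, lag: int) -> int:
        """Circular autocorrelation of the ±1-mapped sequence at ``lag``.

        For an m-sequence this equals ``L`` at lag 0 and exactly −1 at every
        nonzero lag.  Computed on integers, so the result is exact.
        """
        b = np.asarray(self.bits, dtype=int) * 2 - 1
        return int(np.dot(b, np.roll(b, lag)))


def generate_msequence(
    n_stages: int,
    taps: tuple[int, ...] = DEFAULT_TAPS,
    initial_state: tuple[int, ...] | None = None,
    bit_rate: float = 60.0,
) -> BinaryCode:
    """Generate a maximum-length sequence with a Fibonacci LFSR.

    The register holds ``n_stages`` bits ``(s_1, ..., s_m)``.  At each step
    the output is ``s_m``, the feedback bit is the XOR of the tapped stages,
    and the register shifts right with the feedback entering at ``s_1``.
    With a primitive feedback polynomial the register visits all
    ``2^m - 1`` nonzero states, producing a sequence with
    ``2^(m-1)`` ones and ``2^(m-1) - 1`` zeros.

    Parameters
    ----------
    n_stages
        Register length ``m``; the sequence length is ``2^m - 1``.
    taps
        1-based stage numbers whose XOR forms the feedback (the exponents of
        the feedback polynomial).  Default: ``(6, 5)``, i.e. x^6 + x^5 + 1.
    initial_state
        Nonzero start state ``(s_1, ..., s_m)``; default all-ones.
    bit_rate
        Presentation rate attached to the returned code.

    Raises
    ------
    ValueError
        If the initial state is all zeros, taps are out of range, or the
        measured period is shorter than ``2^m - 1`` (non-primitive taps);
        the error names the measured period.
    """
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if n_stages > 6 and taps == DEFAULT_TAPS:
        raise ValueError("default taps are for n_stages=6; supply taps explicitly")
    if not taps or any(t < 1 or t > n_stages for t in taps):
        raise ValueError(f"taps must be stage numbers in 1..{n_stages}, got {taps}")
    if initial_state is None:
        initial_state = (1,) * n_stages
    state = list(initial_state)
    if len(state) != n_stages:
        raise ValueError("initial_state length must equal n_stages")
    if not any(state):
        raise ValueError("initial_state must not be all zeros")

    length = 2**n_stages - 1
    start = tuple(state)
    bits: list[int] = []
    for step in range(length):
        bits.append(state[-1])
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = [fb] + state[:-1]
        if tuple(state) == start and step + 1 < length:
            raise ValueError(
                f"feedback taps {taps} are not primitive: LFSR period is "
                f"{step + 1}, expected {length}"
            )
    if tuple(state) != start:
        raise ValueError(
            f"feedback taps {taps} are not primitive: state did not return "
            f"to the seed after {length} steps"
        )

    code = BinaryCode(bits=tuple(bits), bit_rate=bit_rate)
    # Defensive verification of the m-sequence balance invariant.
    ones = sum(code.bits)
    if ones != 2 ** (n_stages - 1):
        raise ValueError(f"balance violated: {ones} ones in length {length}")
    return code


def shift_code(code: BinaryCode, lag_bits: int) -> BinaryCode:
    """Circularly rotate a code to the right by ``lag_bits`` (mod L).

    A right rotation delays the sequence: the code of a later target starts
    ``lag_bits`` bit-periods after the base code.  Lags are taken modulo the
    code length, so ``lag_bits=0`` and ``lag_bits=L`` return the identical
    sequence.
    """
    lag = lag_bits % len(code.bits)
    if lag == 0:
        return code
    bits = code.bits[-lag:] + code.bits[:-lag]
    return BinaryCode(bits=bits, bit_rate=code.bit_rate)


@dataclass(frozen=True)
class CodeBook:
    """Per-target modulation codes derived from one base m-sequence.

    Target ``z`` flickers with the base code rotated right by
    ``z * lag_bits`` bits.  ``reference_target`` is the target at which
    training trials are recorded; training data for every other target are
    synthesized by circularly shifting the reference trials.
    """

    base: BinaryCode
    n_targets: int
    lag_bits: int
    reference_target: int = 10
    codes: tuple[BinaryCode, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_targets < 2:
            raise ValueError("n_targets must be >= 2")
        if not 0 <= self.reference_target < self.n_targets:
            raise ValueError("reference_target out of range")
        codes = tuple(
            shift_code(self.base, z * self.lag_bits) for z in range(self.n_targets)
        )
        seen = {c.bits for c in codes}
        if len(seen) != self.n_targets:
            raise ValueError(
                f"degenerate lag structure: only {len(seen)} distinct codes "
                f"for {self.n_targets} targets (lag_bits={self.lag_bits})"
            )
        object.__setattr__(self, "codes", codes)

    @property
    def bit_rate(self) -> float:
        return self.base.bit_rate

    @property
    def period_s(self) -> float:
        """Seconds per stimulus cycle, L / bit_rate."""
        return self.base.period_s

    def lag_of(self, z: int) -> int:
        """Circular lag in bits of target ``z`` relative to the reference."""
        L = len(self.base)
        return ((z - self.reference_target) * self.lag_bits) % L

    def to_json(self) -> str:
        return json.dumps(
            {
                "bits": "".join(str(b) for b in self.base.bits),
                "bit_rate": self.base.bit_rate,
                "n_targets": self.n_targets,
                "lag_bits": self.lag_bits,
                "reference_target": self.reference_target,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CodeBook":
        d = json.loads(text)
        base = BinaryCode(
            bits=tuple(int(c) for c in d["bits"]), bit_rate=float(d["bit_rate"])
        )
        return cls(
            base=base,
            n_targets=int(d["n_targets"]),
            lag_bits=int(d["lag_bits"]),
            reference_target=int(d["reference_target"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CodeBook":
        return cls.from_json(Path(path).read_text())


def build_codebook(
    base: BinaryCode,
    n_targets: int = 16,
    lag_bits: int = 4,
    bit_rate: float | None = None,
    reference_target: int = 10,
) -> CodeBook:
    """Assemble the per-target codebook from a base code.

    Parameters mirror the standard 16-target layout: a 63-bit m-sequence at
    60 Hz (stimulus period 63/60 = 1.05 s) shifted in 4-bit steps.
    ``bit_rate``, when given, overrides the rate stored on ``base``.
    """
    if bit_rate is not None and bit_rate != base.bit_rate:
        base = BinaryCode(bits=base.bits, bit_rate=bit_rate)
    return CodeBook(
        base=base,
        n_targets=n_targets,
        lag_bits=lag_bits,
        reference_target=reference_target,
    )


def default_codebook(bit_rate: float = 60.0) -> CodeBook:
    """The study-default codebook: 63-bit m-sequence, 16 targets, 4-bit lags."""
    base = generate_msequence(6, bit_rate=bit_rate)
    return build_codebook(base, n_targets=16, lag_bits=4, reference_target=10)
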