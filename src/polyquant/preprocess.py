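"""Signal conditioning: smoothing, baseline subtraction, second differences.

The smoothing kernel is a centered moving average whose window is the
single "degree of smoothing" knob; at the trace edges the window shrinks
symmetrically to the largest odd width that fits, so output length equals
input length and smoothing never leaves the input's value range. Because
both smoothing and baseline subtraction are linear, their order is
irrelevant.

The discrete second difference d2[i] = y[i+1] - 2 y[i] + y[i-1] drives both
inflection-point detection and deconvolution peak seeding. Its output index
``i`` corresponds to input index ``i + 1``; :data:`SECOND_DIFF_OFFSET`
exposes that mapping so seed positions always refer to the original axis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Baseline, as_trace
from .errors import ValidationError

__all__ = [
    "SmoothingSpec",
    "smooth",
    "subtract_baseline",
    "baseline_from_index",
    "second_difference",
    "SECOND_DIFF_OFFSET",
]

#: second_difference output index i refers to input index i + SECOND_DIFF_OFFSET.
SECOND_DIFF_OFFSET = 1


@dataclass(frozen=True)
class SmoothingSpec:
    """Moving-average window width in samples; odd, >= 1 (1 = no smoothing)."""

    window: int = 1

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError(f"smoothing window must be odd and >= 1, got {self.window}")

    def validate_for(self, trace: np.ndarray) -> None:
        if self.window > len(trace):
            raise ValidationError(
                f"smoothing window {self.window} exceeds trace length {len(trace)}"
            )


def smooth(trace, spec: SmoothingSpec | int = 1) -> np.ndarray:
    """Centered moving average with symmetric edge shrinking.

    At index ``i`` the half-width is ``min(window//2, i, L-1-i)``, i.e. the
    window shrinks to the largest odd width fitting inside the trace.
    ``window=1`` returns the input unchanged (as a copy).
    """
    if isinstance(spec, int):
        spec = SmoothingSpec(spec)
    y = as_trace(trace)
    spec.validate_for(y)
    if spec.window == 1:
        return y.copy()
    n = len(y)
    idx = np.arange(n)
    half = np.minimum(np.minimum(idx, n - 1 - idx), spec.window // 2)
    csum = np.concatenate(([0.0], np.cumsum(y)))
    return (csum[idx + half + 1] - csum[idx - half]) / (2 * half + 1)


def subtract_baseline(trace, baseline: Baseline) -> np.ndarray:
    """y'[i] = y[i] - b. Negative results are permitted (and meaningful:
    they flag a baseline set above the signal)."""
    y = as_trace(trace)
    return y - baseline.value


def baseline_from_index(trace, index: int, window: int = 1, channel: str = "uv") -> Baseline:
    """Read a baseline level from the trace at ``index``.

    The value is the mean of the centered window at ``index`` (shrunk
    symmetrically at the edges); ``window=1`` takes the raw sample value.
    The conventional choice is the end of the profile, where the gradient
    has eluted completely but sucrose solution still passes the detector.
    """
    y = as_trace(trace)
    if not 0 <= index < len(y):
        raise ValidationError(f"baseline index {index} out of range [0, {len(y)})")
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"baseline window must be odd and >= 1, got {window}")
    half = min(window // 2, index, len(y) - 1 - index)
    value = float(np.mean(y[index - half : index + half + 1]))
    return Baseline(channel=channel, value=value, source_index=index)


def second_difference(trace) -> np.ndarray:
    """Discrete second difference; output length L - 2.

    Output index ``i`` corresponds to input index ``i + 1``
    (:data:`SECOND_DIFF_OFFSET`).
    """
    y = as_trace(trace)
    return np.diff(y, n=2)
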