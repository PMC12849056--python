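"""Shared domain types: traces, profiles, baselines, regions.

A *trace* is an ordered, unit-spaced sequence of signal values for one
detector channel (UV absorbance at ~260 nm, or fluorescence). The x-axis is
the 0-based sample index; no attempt is made to parse time or volume
columns, because alignment and quantification operate on data-point
position. A *profile* is one gradient run: a UV trace, optionally a
fluorescence trace recorded row-for-row alongside it, plus import metadata
and per-channel baselines.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = ["as_trace", "Baseline", "Profile", "Region", "CHANNELS"]

CHANNELS = ("uv", "fluor")

#: Minimum trace length: second differences must exist.
MIN_TRACE_LEN = 3


def as_trace(values, *, what: str = "trace") -> np.ndarray:
    """Coerce ``values`` to a validated float64 trace array.

    Raises :class:`ValidationError` if the result is shorter than 3 samples
    or contains non-finite values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional, got shape {arr.shape}")
    if arr.size < MIN_TRACE_LEN:
        raise ValidationError(
            f"{what} has {arr.size} samples; at least {MIN_TRACE_LEN} are required"
        )
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"{what} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True)
class Baseline:
    """A single scalar baseline level for one channel.

    The baseline is the signal attributable to buffer/sucrose rather than
    RNA (or to detector background, for fluorescence) and is subtracted from
    the channel before every downstream step. ``source_index`` records the
    sample it was read from, when it came from the trace itself.
    """

    channel: str
    value: float
    source_index: int | None = None

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not np.isfinite(self.value):
            raise ValidationError("baseline value must be finite")


@dataclass
class Profile:
    """One imported gradient run.

    ``uv`` is required; ``fluor``, when present, has the same length (the
    two channels are stored as two columns with corresponding measurements
    in the same row). ``baselines`` maps channel name to its
    :class:`Baseline`; the fluorescence baseline is independent of the UV
    baseline.
    """

    id: str
    uv: np.ndarray
    fluor: np.ndarray | None = None
    source: str | None = None
    dialect_name: str | None = None
    condition: str | None = None
    baselines: dict[str, Baseline] = field(default_factory=dict)

    def __post_init__(self):
        self.uv = as_trace(self.uv, what="uv trace")
        if self.fluor is not None:
            self.fluor = as_trace(self.fluor, what="fluorescence trace")
            if len(self.fluor) != len(self.uv):
                raise ValidationError(
                    f"fluorescence trace length {len(self.fluor)} does not match "
                    f"UV trace length {len(self.uv)}"
                )

    def __len__(self) -> int:
        return len(self.uv)

    def channel(self, name: str) -> np.ndarray:
        if name == "uv":
            return self.uv
        if name == "fluor":
            if self.fluor is None:
                raise ValidationError(f"profile {self.id!r} has no fluorescence channel")
            return self.fluor
        raise ValidationError(f"unknown channel {name!r}")

    def set_baseline(self, baseline: Baseline) -> None:
        self.baselines[baseline.channel] = baseline

    def with_channel(self, name: str, values: np.ndarray) -> "Profile":
        """Return a copy with channel ``name`` replaced by ``values``."""
        if name == "uv":
            return replace(self, uv=values, baselines=dict(self.baselines))
        if name == "fluor":
            return replace(self, fluor=values, baselines=dict(self.baselines))
        raise ValidationError(f"unknown channel {name!r}")


@dataclass(frozen=True)
class Region:
    """A labeled closed index interval [start, end] on one profile channel.

    Both endpoints are included: the quantified area is the sum of the
    baseline-subtracted values from ``start`` to ``end`` inclusive. Typical
    labels follow field usage: "Total" (40S peak to end of profile),
    "Polysomes" (disomes to end), "60S", ...
    """

    label: str
    start: int
    end: int
    channel: str = "uv"

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if not (0 <= self.start <= self.end):
            raise ValidationError(
                f"region {self.label!r}: need 0 <= start <= end, got [{self.start}, {self.end}]"
            )

    def validate_for(self, trace: np.ndarray) -> None:
        if self.end >= len(trace):
            raise ValidationError(
                f"region {self.label!r} [{self.start}, {self.end}] exceeds trace "
                f"of length {len(trace)}"
            )

    @property
    def length(self) -> int:
        """Number of samples in the closed interval."""
        return self.end - self.start + 1
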