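"""Detection of local minima, maxima and inflection points.

A sample ``i`` is a local minimum at resolution ``r`` iff
``y[i] <= y[j]`` for every ``j`` with ``|j - i| <= r`` (clipped to the
trace), with strict inequality for at least one such ``j``; maxima dually.
The half-window ``r`` is the "resolution" knob: raising it thins the
feature set, suppressing noise-scale wiggles. Plateaus are reported at
their leftmost index. Inflection points are sign changes of the discrete
second difference, reported at the left sample of the crossing pair on the
original axis; the half-window does not enter their definition.

:func:`snap` is the headless equivalent of clicking near a feature in an
interactive plot: it moves an approximate position to the nearest detected
feature (ties broken toward the smaller index).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .core import as_trace
from .errors import FeatureNotFoundError, ValidationError
from .preprocess import SECOND_DIFF_OFFSET, second_difference

__all__ = ["FeatureKind", "ResolutionSpec", "find_features", "snap"]


class FeatureKind(str, enum.Enum):
    MINIMUM = "minimum"
    MAXIMUM = "maximum"
    INFLECTION = "inflection"


@dataclass(frozen=True)
class ResolutionSpec:
    """Half-window ``r`` for the local-extremum test; 1 <= r < L/2."""

    half_window: int = 1

    def __post_init__(self):
        if self.half_window < 1:
            raise ValidationError(f"half_window must be >= 1, got {self.half_window}")

    def validate_for(self, trace: np.ndarray) -> None:
        if self.half_window >= len(trace) / 2:
            raise ValidationError(
                f"half_window {self.half_window} must be < L/2 = {len(trace) / 2}"
            )


def _extrema(y: np.ndarray, r: int, *, minima: bool) -> list[int]:
    if not minima:
        y = -y
    size = 2 * r + 1
    # mode="nearest" replicates edge samples, so the filtered value over a
    # window clipped at the boundary equals the min/max of the in-range part.
    wmin = minimum_filter1d(y, size=size, mode="nearest")
    wmax = maximum_filter1d(y, size=size, mode="nearest")
    qualifies = (y == wmin) & (wmax > y)
    out: list[int] = []
    for i in np.flatnonzero(qualifies):
        i = int(i)
        # Leftmost-index plateau reporting: drop i if it continues a plateau
        # whose leftmost qualifying index was already kept.
        if out and y[i] == y[out[-1]] and np.all(y[out[-1] : i + 1] == y[i]):
            continue
        out.append(i)
    return out


def _inflections(y: np.ndarray) -> list[int]:
    d2 = second_difference(y)
    signs = np.sign(d2)
    nz = np.flatnonzero(signs)
    out: list[int] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            # Left sample of the crossing pair, mapped to the original axis.
            out.append(int(a) + SECOND_DIFF_OFFSET)
    return out


def find_features(trace, kind: FeatureKind | str, res: ResolutionSpec | int = 1) -> list[int]:
    """Indices of all features of ``kind``, sorted ascending, duplicate-free."""
    if isinstance(res, int):
        res = ResolutionSpec(res)
    kind = FeatureKind(kind)
    y = as_trace(trace)
    res.validate_for(y)
    if kind is FeatureKind.MINIMUM:
        return _extrema(y, res.half_window, minima=True)
    if kind is FeatureKind.MAXIMUM:
        return _extrema(y, res.half_window, minima=False)
    return _inflections(y)


def snap(trace, approx: int, kind: FeatureKind | str, res: ResolutionSpec | int = 1) -> int:
    """Snap an approximate position to the nearest feature of ``kind``.

    Ties are broken toward the smaller index, so snapping is deterministic
    and session replays are exact.
    """
    y = as_trace(trace)
    if not 0 <= approx < len(y):
        raise ValidationError(f"approx index {approx} out of range [0, {len(y)})")
    feats = find_features(y, kind, res)
    if not feats:
        raise FeatureNotFoundError(
            f"no {FeatureKind(kind).value} found; lower the resolution half-window "
            "or use the raw index"
        )
    return min(feats, key=lambda i: (abs(i - approx), i))
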