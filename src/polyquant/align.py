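"""Alignment of multiple profiles along per-profile x-anchors, with optional
normalization of total area and profile length.

Profiles from different runs (or different instruments) are shifted along
the x-axis so that a chosen anchor position — conventionally the valley
between the monosome and the disome peak — falls at the same aligned
x-value for every profile. Alignment is integer shifting of data-point
positions only; no resampling or warping is performed at the anchor.

Because the amount of material on the gradient, detector sensitivity and
elution speed vary between runs, the y-scale and x-resolution of profiles
may also be normalized: each profile's user-defined "Total" area can be
rescaled to the largest (or the longest) Total among the profiles, and the
profile stretched/shrunk along x by a constant factor with linear
interpolation. Region and anchor indices are remapped by the same stretch
factor so downstream quantification stays consistent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Baseline, Profile, Region
from .errors import DegenerateInputError, ValidationError
from .quantify import area

__all__ = [
    "Anchor",
    "AlignmentResult",
    "align_profiles",
    "scale_area",
    "stretch_length",
    "remap_index",
    "normalize_profiles",
    "overlay_table",
]


@dataclass(frozen=True)
class Anchor:
    """A per-profile alignment position on that profile's own index axis."""

    profile_id: str
    index: int

    def __post_init__(self):
        if self.index < 0:
            raise ValidationError(f"anchor index must be >= 0, got {self.index}")


@dataclass
class AlignmentResult:
    """Integer x-offsets (and optional normalization factors) per profile.

    After applying ``offsets``, every anchor maps to ``aligned_x``. Factors
    are 1 when normalization is disabled.
    """

    aligned_x: int
    offsets: dict[str, int]
    area_factors: dict[str, float] = field(default_factory=dict)
    length_factors: dict[str, float] = field(default_factory=dict)
    reference_id: str | None = None

    def __post_init__(self):
        for pid in self.offsets:
            self.area_factors.setdefault(pid, 1.0)
            self.length_factors.setdefault(pid, 1.0)


def align_profiles(profiles: list[Profile], anchors: list[Anchor]) -> AlignmentResult:
    """Compute integer offsets placing every anchor at the same aligned x.

    The common aligned x is the maximum anchor index over all profiles, so
    every offset is non-negative (no profile needs left padding). UV and
    fluorescence channels of a profile share its offset (corresponding
    rows).
    """
    by_id = {a.profile_id: a for a in anchors}
    if len(by_id) != len(anchors):
        raise ValidationError("duplicate anchor for a profile")
    ids = [p.id for p in profiles]
    missing = [pid for pid in ids if pid not in by_id]
    if missing:
        raise ValidationError(f"missing anchors for profiles: {missing}")
    extra = set(by_id) - set(ids)
    if extra:
        raise ValidationError(f"anchors reference unknown profiles: {sorted(extra)}")
    for p in profiles:
        if by_id[p.id].index >= len(p):
            raise ValidationError(
                f"anchor {by_id[p.id].index} out of range for profile {p.id!r} "
                f"of length {len(p)}"
            )
    aligned_x = max(by_id[pid].index for pid in ids)
    offsets = {pid: aligned_x - by_id[pid].index for pid in ids}
    return AlignmentResult(aligned_x=aligned_x, offsets=offsets)


def scale_area(
    profile: Profile, total: Region, reference_area: float, baseline: Baseline
) -> tuple[Profile, float]:
    """Rescale the baseline-subtracted channel so the Total area equals
    ``reference_area``.

    Returns ``(scaled_profile, f)`` with ``f = reference_area / own_total``;
    the stored values become ``b + f * (y - b)`` so re-quantifying with the
    same baseline yields exactly the reference area (within float
    round-off).
    """
    if reference_area <= 0:
        raise ValidationError(f"reference_area must be positive, got {reference_area}")
    y = profile.channel(total.channel)
    own = area(y, total, baseline)
    if own <= 0:
        raise DegenerateInputError(
            f"profile {profile.id!r}: total area {own:.4g} is not positive; "
            "check the baseline and region"
        )
    f = reference_area / own
    scaled = baseline.value + f * (y - baseline.value)
    return profile.with_channel(total.channel, scaled), f


def stretch_length(profile: Profile, factor: float) -> Profile:
    """Resample all channels onto round(factor * L) evenly spaced positions
    over the original index range, by linear interpolation.

    Endpoints are preserved exactly; UV and fluorescence are stretched by
    the same factor.
    """
    if factor <= 0:
        raise ValidationError(f"stretch factor must be positive, got {factor}")
    n_old = len(profile)
    n_new = int(round(factor * n_old))
    if n_new < 3:
        raise ValidationError(f"stretched length {n_new} is below the minimum of 3")
    x_old = np.arange(n_old, dtype=float)
    x_new = np.linspace(0.0, n_old - 1.0, n_new)
    from dataclasses import replace

    return replace(
        profile,
        uv=np.interp(x_new, x_old, profile.uv),
        fluor=np.interp(x_new, x_old, profile.fluor) if profile.fluor is not None else None,
        baselines=dict(profile.baselines),
    )


def remap_index(index: int, old_length: int, new_length: int) -> int:
    """Map a sample index through a length change (round to nearest)."""
    if old_length < 2 or new_length < 2:
        raise ValidationError("lengths must be >= 2 to remap indices")
    return int(round(index * (new_length - 1) / (old_length - 1)))


def normalize_profiles(
    profiles: list[Profile],
    totals: dict[str, Region],
    mode: str = "largest",
) -> tuple[list[Profile], dict[str, float], dict[str, float], str]:
    """Adjust every profile's Total to a common reference.

    ``mode="largest"`` rescales y so all Total areas equal the maximal Total
    area; ``mode="longest"`` stretches x so all Total regions have the
    sample count of the longest one; ``mode="none"`` is the identity. Ties
    go to the first profile in input order. Returns
    ``(profiles, area_factors, length_factors, reference_id)``.

    Each profile must already carry a baseline for its Total's channel.
    """
    if mode not in ("largest", "longest", "none"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    area_factors = {p.id: 1.0 for p in profiles}
    length_factors = {p.id: 1.0 for p in profiles}
    if mode == "none":
        return list(profiles), area_factors, length_factors, ""
    for p in profiles:
        if p.id not in totals:
            raise ValidationError(f"no Total region for profile {p.id!r}")
    if mode == "largest":
        own = {
            p.id: area(p.channel(totals[p.id].channel), totals[p.id], p.baselines[totals[p.id].channel])
            for p in profiles
        }
        ref_id = max(profiles, key=lambda p: own[p.id]).id  # max is stable: first wins ties
        out = []
        for p in profiles:
            scaled, f = scale_area(
                p, totals[p.id], own[ref_id], p.baselines[totals[p.id].channel]
            )
            area_factors[p.id] = f
            out.append(scaled)
        return out, area_factors, length_factors, ref_id
    # mode == "longest": stretch so every Total spans the reference's sample count
    lengths = {p.id: totals[p.id].length for p in profiles}
    ref_id = max(profiles, key=lambda p: lengths[p.id]).id
    out = []
    for p in profiles:
        f = lengths[ref_id] / lengths[p.id]
        length_factors[p.id] = f
        out.append(stretch_length(p, f) if f != 1.0 else p)
    return out, area_factors, length_factors, ref_id


def overlay_table(profiles: list[Profile], result: AlignmentResult) -> pd.DataFrame:
    """Wide table of aligned traces: column ``x`` plus one column per
    profile channel (``<id>_uv``, ``<id>_fluor``), shifted by the profile's
    offset; positions a profile does not cover are NaN."""
    width = max(result.offsets[p.id] + len(p) for p in profiles)
    data: dict[str, np.ndarray] = {"x": np.arange(width)}
    for p in profiles:
        off = result.offsets[p.id]
        for channel in ("uv", "fluor"):
            if channel == "fluor" and p.fluor is None:
                continue
            col = np.full(width, np.nan)
            col[off : off + len(p)] = p.channel(channel)
            data[f"{p.id}_{channel}"] = col
    return pd.DataFrame(data)
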