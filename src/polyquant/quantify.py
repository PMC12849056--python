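"""Area quantification of profile subsections and replicate summaries.

The area under a profile subsection is approximated by the sum of the
baseline-subtracted data points over the closed interval [start, end] —
a pure sum with no x-spacing multiplier, so units are signal x samples.
Relative areas (e.g. polysomes / total, the standard global-translation
readout) are dimensionless and independent of detector sensitivity.
Negative areas are reported, not clamped: they flag a baseline set above
the signal, which the user should see.

Replicates are summarized per condition with the sample standard deviation
(n - 1 denominator), matching small biological replicate counts; no
hypothesis testing is performed here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Baseline, Profile, Region, as_trace
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "AreaResult",
    "SummaryRow",
    "area",
    "quantify_profile",
    "relative_area",
    "summarize",
    "results_table",
    "summary_table",
]


@dataclass(frozen=True)
class AreaResult:
    profile_id: str
    region_label: str
    channel: str
    start: int
    end: int
    baseline: float
    raw_area: float
    relative_to: str | None = None
    relative_area: float | None = None


@dataclass(frozen=True)
class SummaryRow:
    condition: str
    region_label: str
    channel: str
    relative_to: str | None
    mean: float
    sd: float
    n: int


def area(trace, region: Region, baseline: Baseline) -> float:
    """Sum of (y[i] - b) over the closed interval [region.start, region.end].

    The accumulation is an explicit left-to-right loop so the result is
    bit-for-bit reproducible across NumPy versions and summation orders.
    """
    y = as_trace(trace)
    region.validate_for(y)
    if baseline.channel != region.channel:
        raise ValidationError(
            f"baseline channel {baseline.channel!r} does not match region channel "
            f"{region.channel!r}"
        )
    b = baseline.value
    total = 0.0
    for v in y[region.start : region.end + 1]:
        total += float(v) - b
    if total < 0:
        warnings.warn(
            f"negative area {total:.4g} for region {region.label!r}; "
            "the baseline may be set above the signal",
            stacklevel=2,
        )
    return total


def quantify_profile(profile: Profile, regions: list[Region]) -> list[AreaResult]:
    """Quantify every region on its declared channel of one profile.

    Each channel must have a baseline set on the profile. Regions defined on
    the UV axis may be duplicated onto the fluorescence channel by the
    caller; index ranges are shared between channels (corresponding rows).
    """
    labels = [(r.label, r.channel) for r in regions]
    if len(set(labels)) != len(labels):
        raise ValidationError("region labels must be unique per channel")
    out = []
    for region in regions:
        if region.channel not in profile.baselines:
            raise ValidationError(
                f"profile {profile.id!r} has no baseline for channel {region.channel!r}"
            )
        baseline = profile.baselines[region.channel]
        raw = area(profile.channel(region.channel), region, baseline)
        out.append(
            AreaResult(
                profile_id=profile.id,
                region_label=region.label,
                channel=region.channel,
                start=region.start,
                end=region.end,
                baseline=baseline.value,
                raw_area=raw,
            )
        )
    return out


def relative_area(
    results: list[AreaResult], numerator_label: str, denominator_label: str
) -> list[AreaResult]:
    """Fill relative_area = raw(numerator) / raw(denominator) per profile/channel.

    Returns one result per (profile, channel) pair that carries the
    numerator label, with the ratio attached; other results pass through
    unchanged.
    """
    by_key: dict[tuple[str, str], dict[str, AreaResult]] = {}
    for r in results:
        by_key.setdefault((r.profile_id, r.channel), {})[r.region_label] = r
    out: list[AreaResult] = []
    for r in results:
        if r.region_label != numerator_label:
            out.append(r)
            continue
        group = by_key[(r.profile_id, r.channel)]
        if denominator_label not in group:
            raise ValidationError(
                f"profile {r.profile_id!r} channel {r.channel!r} has no region "
                f"{denominator_label!r} to normalize against"
            )
        denom = group[denominator_label].raw_area
        if denom == 0:
            raise DegenerateInputError(
                f"zero denominator area ({denominator_label!r}) for profile {r.profile_id!r}"
            )
        out.append(replace(r, relative_to=denominator_label, relative_area=r.raw_area / denom))
    if not any(r.relative_to == denominator_label for r in out):
        raise ValidationError(f"no region labeled {numerator_label!r} in results")
    return out


def summarize(
    results: list[AreaResult], conditions: dict[str, str] | None = None
) -> list[SummaryRow]:
    """Group results by (condition, region label, channel, normalization mode)
    and report mean, sample sd (n-1; 0 when n=1) and replicate count.

    ``conditions`` maps profile_id to a condition label; every profile in
    ``results`` must be mapped (profiles already carrying a condition can be
    passed via :func:`results_table` instead).
    """
    conditions = conditions or {}
    groups: dict[tuple[str, str, str, str | None], list[float]] = {}
    for r in results:
        if r.profile_id not in conditions:
            raise ValidationError(f"profile {r.profile_id!r} has no condition assigned")
        value = r.relative_area if r.relative_to is not None else r.raw_area
        key = (conditions[r.profile_id], r.region_label, r.channel, r.relative_to)
        groups.setdefault(key, []).append(float(value))
    rows = []
    for (cond, label, channel, rel), values in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        arr = np.asarray(values)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        rows.append(
            SummaryRow(
                condition=cond,
                region_label=label,
                channel=channel,
                relative_to=rel,
                mean=float(np.mean(arr)),
                sd=sd,
                n=len(arr),
            )
        )
    return rows


def results_table(
    results: list[AreaResult], conditions: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tidy quantification table (one row per profile x region x channel)."""
    conditions = conditions or {}
    return pd.DataFrame(
        [
            {
                "profile_id": r.profile_id,
                "condition": conditions.get(r.profile_id, ""),
                "channel": r.channel,
                "region_label": r.region_label,
                "start": r.start,
                "end": r.end,
                "baseline": r.baseline,
                "raw_area": r.raw_area,
                "relative_to": r.relative_to if r.relative_to is not None else "",
                "relative_area": r.relative_area if r.relative_area is not None else "",
            }
            for r in results
        ]
    )


def summary_table(rows: list[SummaryRow]) -> pd.DataFrame:
    """Tidy summary table suitable for (grouped) bar plotting."""
    return pd.DataFrame(
        [
            {
                "condition": s.condition,
                "region_label": s.region_label,
                "channel": s.channel,
                "relative_to": s.relative_to if s.relative_to is not None else "",
                "mean": s.mean,
                "sd": s.sd,
                "n": s.n,
            }
            for s in rows
        ]
    )
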