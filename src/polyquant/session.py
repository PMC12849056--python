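"""Whole-analysis sessions: export, re-import, and headless replay.

A session document records every parameter of an analysis — input files and
their dialects, smoothing, baselines, anchors, regions, normalization mode,
condition labels and deconvolution settings — as a single human-readable
YAML file with a schema version. Re-importing a session and re-running it
on the same input files reproduces the quantification tables bit for bit,
so every step of a published analysis is documented and replayable.

Unknown schema versions are rejected outright, never silently migrated.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .align import Anchor, align_profiles, normalize_profiles, overlay_table
from .core import Baseline, Profile, Region
from .errors import SchemaVersionError, SessionError, ValidationError
from .io_dialects import DialectSpec, read_profile
from .preprocess import SmoothingSpec, smooth
from .quantify import (
    quantify_profile,
    relative_area,
    results_table,
    summarize,
    summary_table,
)

__all__ = [
    "SCHEMA_VERSION",
    "RegionSpec",
    "DeconvolutionSpec",
    "ProfileEntry",
    "AnalysisSession",
    "export_session",
    "import_session",
    "run_session",
]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class RegionSpec:
    label: str
    start: int
    end: int
    channel: str = "uv"

    def to_region(self) -> Region:
        return Region(label=self.label, start=self.start, end=self.end, channel=self.channel)


@dataclass(frozen=True)
class DeconvolutionSpec:
    """Parameters of one user-guided deconvolution run."""

    profile_id: str
    region: RegionSpec
    smoothing_window: int = 7
    half_window: int = 3
    fit_smoothed: bool = False
    seeds: tuple[int, ...] | None = None  # None: re-seed from the data


@dataclass
class ProfileEntry:
    """Everything recorded per imported profile."""

    id: str
    path: str
    dialect: DialectSpec
    condition: str = ""
    smoothing_window: int = 1
    baselines: dict[str, float] = field(default_factory=dict)  # channel -> value
    baseline_sources: dict[str, int | None] = field(default_factory=dict)
    anchor: int | None = None
    regions: list[RegionSpec] = field(default_factory=list)
    area_factor: float = 1.0
    length_factor: float = 1.0


@dataclass
class AnalysisSession:
    """The complete, replayable parameter state of an analysis."""

    profiles: list[ProfileEntry] = field(default_factory=list)
    reference_mode: str = "none"  # largest | longest | none
    relative: tuple[str, str] | None = None  # (numerator label, denominator label)
    deconvolutions: list[DeconvolutionSpec] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self):
        if self.reference_mode not in ("largest", "longest", "none"):
            raise ValidationError(f"unknown reference_mode {self.reference_mode!r}")
        ids = [p.id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate profile ids in session")


def _session_to_doc(session: AnalysisSession) -> dict:
    doc = asdict(session)
    # asdict turns tuples into lists already; keep YAML plain
    return doc


def _entry_from_doc(doc: dict) -> ProfileEntry:
    d = dict(doc)
    dial = d.pop("dialect")
    entry = ProfileEntry(dialect=DialectSpec(**dial), **{**d, "regions": []})
    entry.regions = [RegionSpec(**r) for r in doc.get("regions", [])]
    return entry


def export_session(session: AnalysisSession, path: str | Path) -> Path:
    """Write the session as a YAML document."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(_session_to_doc(session), sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )
    return path


def import_session(path: str | Path) -> AnalysisSession:
    """Read a session document; rejects unknown schema versions."""
    path = Path(path)
    if not path.is_file():
        raise SessionError(f"session file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SessionError(f"cannot parse session {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SessionError(f"session {path} is not a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"session schema_version {version!r} is not supported "
            f"(expected {SCHEMA_VERSION!r}); sessions are never migrated silently"
        )
    try:
        profiles = [_entry_from_doc(p) for p in doc.get("profiles", [])]
        deconvs = []
        for d in doc.get("deconvolutions", []):
            d = dict(d)
            d["region"] = RegionSpec(**d["region"])
            if d.get("seeds") is not None:
                d["seeds"] = tuple(d["seeds"])
            deconvs.append(DeconvolutionSpec(**d))
        relative = doc.get("relative")
        return AnalysisSession(
            profiles=profiles,
            reference_mode=doc.get("reference_mode", "none"),
            relative=tuple(relative) if relative else None,
            deconvolutions=deconvs,
            schema_version=version,
        )
    except (TypeError, KeyError) as exc:
        raise SessionError(f"malformed session {path}: {exc}") from exc


def _load_entry(entry: ProfileEntry) -> Profile:
    p = Path(entry.path)
    if not p.is_file():
        raise SessionError(f"session references a missing input file: {p}")
    profile = read_profile(p, entry.dialect, id=entry.id)
    profile.condition = entry.condition
    if entry.smoothing_window > 1:
        spec = SmoothingSpec(entry.smoothing_window)
        profile.uv = smooth(profile.uv, spec)
        if profile.fluor is not None:
            profile.fluor = smooth(profile.fluor, spec)
    for channel, value in entry.baselines.items():
        profile.set_baseline(
            Baseline(
                channel=channel,
                value=value,
                source_index=entry.baseline_sources.get(channel),
            )
        )
    return profile


def run_session(session: AnalysisSession, outdir: str | Path) -> dict[str, Path]:
    """Replay a session: load inputs, quantify, summarize, deconvolve, align.

    Writes ``areas.csv`` and ``summary.csv`` (and, when configured,
    ``peaks.csv`` and ``overlay.csv``) under ``outdir`` and returns the
    paths. Deterministic: identical session + input files give byte-identical
    outputs.
    """
    from .deconvolve import fit_gaussians, seed_peaks
    from .features import ResolutionSpec

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = [_load_entry(e) for e in session.profiles]
    by_id = {p.id: p for p in profiles}
    out: dict[str, Path] = {}

    # optional normalization of Total areas/lengths before quantification
    totals = {
        e.id: next((r.to_region() for r in e.regions if r.label == "Total"), None)
        for e in session.profiles
    }
    if session.reference_mode != "none":
        missing = [pid for pid, r in totals.items() if r is None]
        if missing:
            raise SessionError(
                f"reference_mode {session.reference_mode!r} needs a 'Total' region "
                f"for every profile; missing for: {missing}"
            )
        profiles, _, _, _ = normalize_profiles(
            profiles, {k: v for k, v in totals.items() if v is not None}, session.reference_mode
        )
        by_id = {p.id: p for p in profiles}

    results = []
    for entry in session.profiles:
        if not entry.regions:
            continue
        regions = [r.to_region() for r in entry.regions]
        results.extend(quantify_profile(by_id[entry.id], regions))
    if session.relative is not None and results:
        results = relative_area(results, session.relative[0], session.relative[1])
    conditions = {e.id: e.condition for e in session.profiles}
    if results:
        out["areas"] = outdir / "areas.csv"
        results_table(results, conditions).to_csv(out["areas"], index=False)
        rows = summarize(results, conditions)
        out["summary"] = outdir / "summary.csv"
        summary_table(rows).to_csv(out["summary"], index=False)

    if session.deconvolutions:
        import pandas as pd

        frames = []
        for spec in session.deconvolutions:
            profile = by_id[spec.profile_id]
            baseline = profile.baselines.get("uv")
            if baseline is None:
                raise SessionError(
                    f"deconvolution of {spec.profile_id!r} needs a UV baseline"
                )
            region = spec.region.to_region()
            seeds = (
                list(spec.seeds)
                if spec.seeds is not None
                else seed_peaks(
                    profile.uv,
                    baseline,
                    SmoothingSpec(spec.smoothing_window),
                    ResolutionSpec(spec.half_window),
                    region,
                )
            )
            fit = fit_gaussians(
                profile.uv,
                baseline,
                region,
                seeds,
                fit_smoothed=spec.fit_smoothed,
                smoothing=SmoothingSpec(spec.smoothing_window),
            )
            frames.append(fit.to_frame(profile_id=spec.profile_id))
        out["peaks"] = outdir / "peaks.csv"
        pd.concat(frames, ignore_index=True).to_csv(out["peaks"], index=False)

    anchored = [e for e in session.profiles if e.anchor is not None]
    if len(anchored) == len(session.profiles) and anchored:
        alignment = align_profiles(
            profiles, [Anchor(e.id, e.anchor) for e in anchored]
        )
        out["overlay"] = outdir / "overlay.csv"
        overlay_table(profiles, alignment).to_csv(out["overlay"], index=False)
    return out
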