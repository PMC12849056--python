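"""Synthetic polysome profiles with known ground truth.

A real UV absorbance profile from a sucrose-density gradient shows, in
elution order: a large early peak from detergents in the lysis buffer, the
40S and 60S ribosomal-subunit peaks, the 80S monosome peak, and a train of
polysome peaks whose heights decay and whose widths grow with ribosome
number (heavier fractions resolve worse). The generator models each peak
as a Gaussian over the sample-index axis and adds a constant baseline, an
optional linear drift, and i.i.d. Gaussian detector noise; a fluorescence
channel can be derived as a reweighted mixture of the same peaks with its
own baseline and noise, mimicking a tagged factor that co-sediments with
specific ribosomal species.

Every recipe carries full ground truth — exact analytic per-peak areas and
the exact polysomal/total area ratio of the noiseless mixture over stated
index ranges — so parameter- and ratio-recovery of the analysis pipeline
can be tested without any instrument data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Profile, Region
from .deconvolve import GaussianPeak
from .errors import ValidationError

__all__ = ["ProfileRecipe", "GroundTruth", "generate", "default_recipes", "recipe"]


@dataclass(frozen=True)
class ProfileRecipe:
    """Everything needed to generate one synthetic profile deterministically.

    ``peaks`` and ``peak_labels`` run in elution order (ascending mu). The
    conventional labels are "detergent", "40S", "60S", "80S", then
    "P1".."Pn" for n-some polysome peaks (P1 = disome in run order here,
    i.e. the first polysomal peak). ``fluor_weights``, when set, give the
    per-peak height multiplier of the fluorescence channel.
    """

    name: str
    length: int
    baseline: float
    peaks: tuple[GaussianPeak, ...]
    peak_labels: tuple[str, ...]
    noise_sd: float = 0.0
    drift: float = 0.0
    fluor_weights: tuple[float, ...] | None = None
    fluor_baseline: float = 0.0
    fluor_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.length < 3:
            raise ValidationError("profile length must be >= 3")
        if len(self.peaks) != len(self.peak_labels):
            raise ValidationError("peaks and peak_labels must have equal length")
        mus = [p.mu for p in self.peaks]
        if any(not 0 <= m < self.length for m in mus):
            raise ValidationError("every peak mu must lie in [0, length)")
        if any(b >= a for a, b in zip(mus[1:], mus[:-1])):
            raise ValidationError("peaks must be in ascending mu order")
        if self.noise_sd < 0 or self.fluor_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.fluor_weights is not None:
            if len(self.fluor_weights) != len(self.peaks):
                raise ValidationError("fluor_weights must match number of peaks")
            if any(w < 0 for w in self.fluor_weights):
                raise ValidationError("fluor_weights must be non-negative")

    def with_seed(self, rng_seed: int) -> "ProfileRecipe":
        return replace(self, rng_seed=rng_seed)

    def label_index(self, label: str) -> int:
        try:
            return self.peak_labels.index(label)
        except ValueError:
            raise ValidationError(f"recipe {self.name!r} has no peak labeled {label!r}") from None


@dataclass(frozen=True)
class GroundTruth:
    """Exact quantities implied by a recipe (recomputable from it alone)."""

    recipe: ProfileRecipe
    peak_areas: tuple[float, ...]
    total_region: Region
    polysome_region: Region
    polysome_total_ratio: float
    deconvolution_region: Region = field(default=None)  # 40S..80S subunit region


def _mixture(recipe: ProfileRecipe, weights=None) -> np.ndarray:
    x = np.arange(recipe.length, dtype=float)
    out = np.zeros(recipe.length)
    for k, p in enumerate(recipe.peaks):
        w = 1.0 if weights is None else weights[k]
        if w:
            out += w * p(x)
    return out


def _ground_truth(recipe: ProfileRecipe) -> GroundTruth:
    mix = _mixture(recipe)
    i40 = recipe.label_index("40S")
    i80 = recipe.label_index("80S")
    ip1 = recipe.label_index("P1")
    p40, p80, pp1 = recipe.peaks[i40], recipe.peaks[i80], recipe.peaks[ip1]
    # Total: from the leading edge of the 40S peak to the end of the profile;
    # Polysomes: from the monosome/disome valley to the end of the profile.
    total = Region("Total", int(round(p40.mu - 3 * p40.sigma)), recipe.length - 1)
    poly = Region("Polysomes", int(round((p80.mu + pp1.mu) / 2)), recipe.length - 1)
    total_area = float(np.sum(mix[total.start : total.end + 1]))
    poly_area = float(np.sum(mix[poly.start : poly.end + 1]))
    # Subunit region for deconvolution: lower flank of 40S to upper flank of 80S.
    deconv = Region(
        "Subunits",
        int(round(p40.mu - 2 * p40.sigma)),
        int(round(p80.mu + 2 * p80.sigma)),
    )
    return GroundTruth(
        recipe=recipe,
        peak_areas=tuple(p.area for p in recipe.peaks),
        total_region=total,
        polysome_region=poly,
        polysome_total_ratio=poly_area / total_area,
        deconvolution_region=deconv,
    )


def generate(recipe: ProfileRecipe) -> tuple[Profile, GroundTruth]:
    """Generate one profile: uv[i] = b + drift*i + sum_k g_k(i) + noise.

    Deterministic given ``recipe.rng_seed``; the fluorescence channel (if
    ``fluor_weights`` is set) uses the same peaks reweighted, its own
    baseline, and an independent noise stream from the same generator.
    """
    rng = np.random.default_rng(recipe.rng_seed)
    x = np.arange(recipe.length, dtype=float)
    uv = recipe.baseline + recipe.drift * x + _mixture(recipe)
    if recipe.noise_sd > 0:
        uv = uv + rng.normal(0.0, recipe.noise_sd, recipe.length)
    fluor = None
    if recipe.fluor_weights is not None:
        fluor = recipe.fluor_baseline + _mixture(recipe, recipe.fluor_weights)
        if recipe.fluor_noise_sd > 0:
            fluor = fluor + rng.normal(0.0, recipe.fluor_noise_sd, recipe.length)
    profile = Profile(id=recipe.name, uv=uv, fluor=fluor, condition=None)
    return profile, _ground_truth(recipe)


def _standard_peaks(
    length: int = 1000,
    n_poly: int = 6,
    poly_height0: float = 1.2,
    poly_ratio: float = 0.72,
    poly_height_scale: float = 1.0,
    halfmers: bool = False,
) -> tuple[tuple[GaussianPeak, ...], tuple[str, ...]]:
    """Peak layout echoing a mammalian profile on a 1000-sample axis."""
    scale = length / 1000.0
    peaks = [
        GaussianPeak(mu=40 * scale, sigma=12 * scale, height=3.0),   # detergent
        GaussianPeak(mu=180 * scale, sigma=10 * scale, height=0.5),  # 40S
        GaussianPeak(mu=240 * scale, sigma=11 * scale, height=0.7),  # 60S
        GaussianPeak(mu=310 * scale, sigma=13 * scale, height=1.6),  # 80S
    ]
    labels = ["detergent", "40S", "60S", "80S"]
    mu = 420.0 * scale
    spacing = 90.0 * scale
    for k in range(n_poly):
        peaks.append(
            GaussianPeak(
                mu=mu,
                sigma=16.0 * scale * 1.15**k,       # heavier fractions resolve worse
                height=poly_height_scale * poly_height0 * poly_ratio**k,
            )
        )
        labels.append(f"P{k + 1}")
        mu += spacing
        spacing *= 0.9                               # spacing shrinks down the train
    if halfmers:
        # low halfmer shoulders between 80S/P1 and P1/P2
        extra = [
            (GaussianPeak(mu=365 * scale, sigma=8 * scale, height=0.15), "halfmer1"),
            (GaussianPeak(mu=465 * scale, sigma=9 * scale, height=0.10), "halfmer2"),
        ]
        merged = sorted(
            list(zip(peaks, labels)) + extra, key=lambda pl: pl[0].mu
        )
        peaks = [p for p, _ in merged]
        labels = [l for _, l in merged]
    return tuple(peaks), tuple(labels)


def recipe(name: str, rng_seed: int = 0, **overrides) -> ProfileRecipe:
    """Build a named default recipe ("mammalian", "runoff", "halfmer",
    "fluorescent"), optionally overriding any recipe field."""
    length = 1000
    base = dict(
        name=name,
        length=length,
        baseline=0.25,
        noise_sd=0.03,  # 1% of the tallest (detergent) peak
        drift=0.0,
        rng_seed=rng_seed,
    )
    if name == "mammalian":
        peaks, labels = _standard_peaks(length)
    elif name == "runoff":
        # stalled initiation: elongating ribosomes run off, polysomes halve
        peaks, labels = _standard_peaks(length, poly_height_scale=0.5)
    elif name == "halfmer":
        peaks, labels = _standard_peaks(length, halfmers=True)
    elif name == "fluorescent":
        peaks, labels = _standard_peaks(length)
        # tagged factor riding on monosomes/polysomes, absent from the
        # detergent peak and subunits
        weights = []
        for label in labels:
            if label == "80S":
                weights.append(0.2)
            elif label.startswith("P"):
                weights.append(0.4)
            else:
                weights.append(0.0)
        base.update(
            fluor_weights=tuple(weights), fluor_baseline=0.05, fluor_noise_sd=0.004
        )
    else:
        raise ValidationError(
            f"unknown recipe {name!r}; known: mammalian, runoff, halfmer, fluorescent"
        )
    base.update(peaks=peaks, peak_labels=labels)
    base.update(overrides)
    return ProfileRecipe(**base)


def default_recipes(rng_seed: int = 0) -> list[ProfileRecipe]:
    """The four named recipes with default parameters."""
    return [recipe(n, rng_seed=rng_seed) for n in ("mammalian", "runoff", "halfmer", "fluorescent")]
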