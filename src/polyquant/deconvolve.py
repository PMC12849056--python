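"""User-guided Gaussian deconvolution of a profile region.

Neighboring peaks in a polysome profile overlap, so the signal each peak
contributes is ambiguous; within a restricted, well-resolved region the
individual peaks are close to Gaussian and the region can be modeled as a
sum of Gaussians g_k(x) = h_k exp(-(x - mu_k)^2 / (2 sigma_k^2)).

Candidate peak positions are seeded from the negative local minima of the
smoothed second derivative of the baseline-subtracted profile (a sharper
bump in the signal makes a sharper negative dip in its curvature). The fit
is a bounded nonlinear least-squares problem: each position mu_k is
restricted to its seed plus/minus a tolerance of 1% of the entire profile
length (the full trace, even when only a sub-region is fitted), and sigma_k
and h_k are bounded positive. Initialisation is deterministic — positions
at the seeds, heights from the signal at the seeds, widths from the seed
spacing — so a fit is exactly reproducible from its session parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import Baseline, Region, as_trace
from .errors import NoSeedsError, ValidationError
from .features import FeatureKind, ResolutionSpec, find_features
from .preprocess import SECOND_DIFF_OFFSET, SmoothingSpec, second_difference, smooth, subtract_baseline

__all__ = [
    "POSITION_TOLERANCE_FRACTION",
    "GaussianPeak",
    "DeconvolutionFit",
    "seed_peaks",
    "fit_gaussians",
    "peak_area",
]

#: Fitted peak positions are bounded to seed +/- this fraction of the
#: entire profile length.
POSITION_TOLERANCE_FRACTION = 0.01

#: Fitted peaks with height below this fraction of the region maximum are
#: flagged as degenerate (they carry no usable signal) but never dropped.
DEGENERATE_HEIGHT_FRACTION = 1e-6


@dataclass(frozen=True)
class GaussianPeak:
    """One modeled peak: g(x) = height * exp(-(x - mu)^2 / (2 sigma^2)).

    ``mu`` and ``sigma`` are in sample-index units on the original profile
    axis; ``height`` is in baseline-subtracted signal units.
    """

    mu: float
    sigma: float
    height: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")
        if not self.height > 0:
            raise ValidationError(f"height must be positive, got {self.height}")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.height * np.exp(-((x - self.mu) ** 2) / (2.0 * self.sigma**2))

    @property
    def area(self) -> float:
        """Analytic area under the Gaussian: height * sigma * sqrt(2 pi)."""
        return self.height * self.sigma * math.sqrt(2.0 * math.pi)


def peak_area(peak: GaussianPeak) -> float:
    """Analytic area of a fitted Gaussian peak (height * sigma * sqrt(2 pi))."""
    return peak.area


@dataclass
class DeconvolutionFit:
    """Results of a Gaussian-mixture fit to one region.

    Carries the estimated peaks (sorted by position), the fitted curve over
    the region, the residual sum of squares, the optimizer's convergence
    flag, the position bounds that were enforced, and per-peak degeneracy
    flags (height below ``1e-6 x`` the region maximum). ``summary()`` and
    ``to_frame()`` present the estimates; ``plot()`` overlays model and
    data.
    """

    region: Region
    peaks: list[GaussianPeak]
    fitted_curve: np.ndarray
    rss: float
    converged: bool
    seeds: list[int]
    tau: float
    degenerate: list[bool] = field(default_factory=list)
    observed: np.ndarray | None = None

    @property
    def peak_areas(self) -> list[float]:
        return [p.area for p in self.peaks]

    @property
    def residuals(self) -> np.ndarray:
        if self.observed is None:
            raise ValidationError("fit stores no observed data")
        return self.observed - self.fitted_curve

    def to_frame(self, profile_id: str = "") -> pd.DataFrame:
        """One row per fitted peak: position, width, height, analytic area."""
        return pd.DataFrame(
            [
                {
                    "profile_id": profile_id,
                    "region_label": self.region.label,
                    "start": self.region.start,
                    "end": self.region.end,
                    "peak": k + 1,
                    "seed": self.seeds[k],
                    "mu": p.mu,
                    "sigma": p.sigma,
                    "height": p.height,
                    "area": p.area,
                    "degenerate": self.degenerate[k] if self.degenerate else False,
                    "rss": self.rss,
                    "converged": self.converged,
                }
                for k, p in enumerate(self.peaks)
            ]
        )

    def curves_frame(self) -> pd.DataFrame:
        """Observed, fitted and residual curves over the region."""
        x = np.arange(self.region.start, self.region.end + 1)
        data = {"x": x, "fitted": self.fitted_curve}
        if self.observed is not None:
            data["observed"] = self.observed
            data["residual"] = self.observed - self.fitted_curve
        for k, p in enumerate(self.peaks, start=1):
            data[f"peak_{k}"] = p(x)
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [
            f"Gaussian deconvolution of region {self.region.label!r} "
            f"[{self.region.start}, {self.region.end}]",
            f"  peaks: {len(self.peaks)}   rss: {self.rss:.6g}   "
            f"converged: {self.converged}   position tolerance: +/-{self.tau:.3g}",
            f"  {'peak':>4} {'seed':>6} {'mu':>10} {'sigma':>10} {'height':>10} {'area':>12}",
        ]
        for k, p in enumerate(self.peaks):
            flag = "  (degenerate)" if self.degenerate and self.degenerate[k] else ""
            lines.append(
                f"  {k + 1:>4} {self.seeds[k]:>6} {p.mu:>10.3f} {p.sigma:>10.3f} "
                f"{p.height:>10.4g} {p.area:>12.5g}{flag}"
            )
        return "\n".join(lines)

    def plot(self, path=None, ax=None):
        from .plotting import deconvolution_plot

        return deconvolution_plot(self, path=path, ax=ax)


def seed_peaks(
    trace,
    baseline: Baseline,
    smoothing: SmoothingSpec | int,
    res: ResolutionSpec | int,
    region: Region,
) -> list[int]:
    """Candidate peak positions in ``region``, on the original axis.

    Pipeline: subtract baseline -> smooth -> second difference -> local
    minima at the given resolution -> keep strictly negative minima -> map
    back to the original axis -> restrict to the region.
    """
    if isinstance(smoothing, int):
        smoothing = SmoothingSpec(smoothing)
    if isinstance(res, int):
        res = ResolutionSpec(res)
    y = as_trace(trace)
    region.validate_for(y)
    if region.length < smoothing.window:
        raise ValidationError(
            f"region length {region.length} is below the smoothing window {smoothing.window}"
        )
    if region.length < 2 * res.half_window + 1:
        raise ValidationError(
            f"region length {region.length} is below the resolution window "
            f"{2 * res.half_window + 1}"
        )
    d2 = second_difference(smooth(subtract_baseline(y, baseline), smoothing))
    minima = find_features(d2, FeatureKind.MINIMUM, res)
    seeds = [
        i + SECOND_DIFF_OFFSET
        for i in minima
        if d2[i] < 0 and region.start <= i + SECOND_DIFF_OFFSET <= region.end
    ]
    if not seeds:
        raise NoSeedsError(
            f"no negative second-derivative minima in region {region.label!r} "
            f"[{region.start}, {region.end}]; widen the region or adjust "
            "smoothing/resolution"
        )
    return sorted(seeds)


def fit_gaussians(
    trace,
    baseline: Baseline,
    region: Region,
    seeds: list[int],
    *,
    fit_smoothed: bool = False,
    smoothing: SmoothingSpec | int = 1,
) -> DeconvolutionFit:
    """Fit a sum of Gaussians to the baseline-subtracted region signal.

    Each position is bounded to ``seed +/- tau`` with
    ``tau = 0.01 * L`` where ``L`` is the **entire profile length**, not the
    region length; widths and heights are bounded positive. By default the
    raw baseline-subtracted signal is fitted; ``fit_smoothed=True`` fits the
    smoothed signal instead (recorded in sessions).

    Optimizer failure never raises: the fit is returned with
    ``converged=False`` and the best parameters found.
    """
    if isinstance(smoothing, int):
        smoothing = SmoothingSpec(smoothing)
    y_full = as_trace(trace)
    region.validate_for(y_full)
    if not seeds:
        raise ValidationError("at least one seed is required")
    seeds = sorted(int(s) for s in seeds)
    for s in seeds:
        if not region.start <= s <= region.end:
            raise ValidationError(
                f"seed {s} lies outside region [{region.start}, {region.end}]"
            )
    if region.length < 3 * len(seeds):
        raise ValidationError(
            f"region length {region.length} is too short for {len(seeds)} peaks "
            f"(need >= {3 * len(seeds)} samples: 3 data points per 3-parameter peak)"
        )

    signal = subtract_baseline(y_full, baseline)
    if fit_smoothed:
        signal = smooth(signal, smoothing)
    x = np.arange(region.start, region.end + 1, dtype=float)
    y = signal[region.start : region.end + 1]

    tau = POSITION_TOLERANCE_FRACTION * len(y_full)
    region_len = float(region.length)
    region_max = float(np.max(y)) if np.max(y) > 0 else 1.0
    height_floor = 1e-6 * region_max

    k = len(seeds)
    mu0 = np.array(seeds, dtype=float)
    h0 = np.maximum(y[np.array(seeds) - region.start], height_floor)
    if k == 1:
        sig0 = np.array([region_len / 4.0])
    else:
        gaps = np.diff(mu0)
        nearest = np.minimum(
            np.concatenate(([gaps[0]], gaps)), np.concatenate((gaps, [gaps[-1]]))
        )
        sig0 = nearest / 2.0
    sig0 = np.clip(sig0, 0.5, region_len)

    def unpack(p):
        return p[:k], p[k : 2 * k], p[2 * k :]

    def model(p):
        mu, sig, h = unpack(p)
        return np.sum(
            h[:, None] * np.exp(-((x[None, :] - mu[:, None]) ** 2) / (2.0 * sig[:, None] ** 2)),
            axis=0,
        )

    def residual(p):
        return model(p) - y

    p0 = np.concatenate([mu0, sig0, h0])
    lower = np.concatenate([mu0 - tau, np.full(k, 1e-6), np.full(k, 1e-12)])
    upper = np.concatenate([mu0 + tau, np.full(k, region_len), np.full(k, np.inf)])
    p0 = np.clip(p0, lower, upper)

    try:
        result = least_squares(
            residual, p0, bounds=(lower, upper), method="trf",
            ftol=1e-12, xtol=1e-12, gtol=1e-12,
        )
        params, converged = result.x, bool(result.success)
    except Exception:
        params, converged = p0, False

    mu, sig, h = unpack(params)
    order = np.argsort(mu)
    peaks = [
        GaussianPeak(mu=float(mu[i]), sigma=float(max(sig[i], 1e-12)), height=float(max(h[i], 1e-300)))
        for i in order
    ]
    fitted = np.sum([p(x) for p in peaks], axis=0)
    rss = float(np.sum((y - fitted) ** 2))
    degenerate = [p.height < DEGENERATE_HEIGHT_FRACTION * region_max for p in peaks]
    return DeconvolutionFit(
        region=region,
        peaks=peaks,
        fitted_curve=fitted,
        rss=rss,
        converged=converged,
        seeds=[seeds[i] for i in order],
        tau=tau,
        degenerate=degenerate,
        observed=y.copy(),
    )
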