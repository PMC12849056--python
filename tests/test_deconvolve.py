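import math

import numpy as np
import pytest
from scipy.integrate import quad

from polyquant import (
    Baseline,
    GaussianPeak,
    NoSeedsError,
    Region,
    ValidationError,
    fit_gaussians,
    peak_area,
    second_difference,
    seed_peaks,
    smooth,
)

from .conftest import (
    THREE_PEAK_L,
    THREE_PEAK_REGION,
    THREE_PEAK_TRUTH,
    three_peak_signal,
)


def gaussian(x, mu, sigma, h):
    return h * np.exp(-((np.asarray(x, dtype=float) - mu) ** 2) / (2 * sigma**2))


def test_peak_area_closed_form():
    assert peak_area(GaussianPeak(0, 1.0, 1.0)) == pytest.approx(math.sqrt(2 * math.pi))
    assert peak_area(GaussianPeak(0, 3.0, 2.0)) == pytest.approx(6 * math.sqrt(2 * math.pi))


def test_peak_area_agrees_with_quadrature():
    peak = GaussianPeak(mu=12.3, sigma=4.5, height=1.7)
    numeric, _ = quad(peak, peak.mu - 8 * peak.sigma, peak.mu + 8 * peak.sigma)
    assert peak_area(peak) == pytest.approx(numeric, rel=1e-6)


def test_invalid_peak_parameters_rejected():
    with pytest.raises(ValidationError):
        GaussianPeak(0, -1.0, 1.0)
    with pytest.raises(ValidationError):
        GaussianPeak(0, 1.0, 0.0)


def brute_force_d2_argmin(y, region):
    d2 = [y[i + 1] - 2 * y[i] + y[i - 1] for i in range(1, len(y) - 1)]
    idx = [i + 1 for i in range(len(d2))]
    pairs = [(v, i) for v, i in zip(d2, idx) if region.start <= i <= region.end]
    return min(pairs)[1]


def test_seed_single_noiseless_gaussian(zero_baseline):
    y = gaussian(np.arange(101), 50, 5, 1.0)
    region = Region("r", 10, 90)
    seeds = seed_peaks(y, zero_baseline, 1, 2, region)
    assert seeds == [50]
    assert brute_force_d2_argmin(y, region) == 50


def test_seed_two_noiseless_gaussians(zero_baseline):
    x = np.arange(101)
    y = gaussian(x, 30, 5, 1.0) + gaussian(x, 70, 5, 0.8)
    seeds = seed_peaks(y, zero_baseline, 1, 2, Region("r", 5, 95))
    assert len(seeds) == 2
    assert abs(seeds[0] - 30) <= 1 and abs(seeds[1] - 70) <= 1


def test_flat_trace_yields_no_seeds(zero_baseline):
    with pytest.raises(NoSeedsError):
        seed_peaks(np.zeros(50), zero_baseline, 1, 2, Region("r", 5, 45))


def test_seed_region_preconditions(zero_baseline):
    y = gaussian(np.arange(101), 50, 5, 1.0)
    with pytest.raises(ValidationError):
        seed_peaks(y, zero_baseline, 11, 2, Region("r", 48, 52))  # region < window
    with pytest.raises(ValidationError):
        seed_peaks(y, zero_baseline, 1, 5, Region("r", 48, 52))  # region < 2r+1


def test_fit_recovers_noiseless_single_gaussian(zero_baseline):
    y = gaussian(np.arange(101), 50, 5, 2.0)
    fit = fit_gaussians(y, zero_baseline, Region("r", 20, 80), [50])
    peak = fit.peaks[0]
    assert peak.mu == pytest.approx(50, abs=0.1)
    assert peak.sigma == pytest.approx(5, abs=0.05)
    assert peak.height == pytest.approx(2, abs=0.02)
    assert fit.rss < 1e-6
    assert fit.converged


def test_fit_noiseless_three_peaks_near_machine_precision(zero_baseline):
    y = three_peak_signal()
    seeds = [int(p.mu) for p in THREE_PEAK_TRUTH]
    fit = fit_gaussians(y, zero_baseline, THREE_PEAK_REGION, seeds)
    assert fit.rss < 1e-6 * float(np.sum(y**2))
    for peak, true in zip(fit.peaks, THREE_PEAK_TRUTH):
        assert peak.mu == pytest.approx(true.mu, rel=0.01)
        assert peak.sigma == pytest.approx(true.sigma, rel=0.01)
        assert peak.height == pytest.approx(true.height, rel=0.01)


def test_position_bound_uses_entire_profile_length(zero_baseline):
    # True peak displaced from its seed by 2% of L; the fitted position must
    # stop at the bound seed + 0.01 * L.
    L = 500
    y = gaussian(np.arange(L), 160, 8, 1.0)
    seed = 150  # displacement 10 = 0.02 * L, tolerance tau = 5
    fit = fit_gaussians(y, zero_baseline, Region("r", 100, 220), [seed])
    tau = 0.01 * L
    assert fit.peaks[0].mu <= seed + tau + 1e-9
    assert fit.peaks[0].mu == pytest.approx(seed + tau, abs=1e-3)


def test_fitted_curve_is_sum_of_peaks(zero_baseline):
    y = three_peak_signal(noise_sd=0.01, seed=3)
    seeds = [int(p.mu) for p in THREE_PEAK_TRUTH]
    fit = fit_gaussians(y, zero_baseline, THREE_PEAK_REGION, seeds)
    x = np.arange(THREE_PEAK_REGION.start, THREE_PEAK_REGION.end + 1)
    manual = sum(p(x) for p in fit.peaks)
    assert np.allclose(fit.fitted_curve, manual, atol=1e-12)
    assert fit.rss == pytest.approx(float(np.sum((fit.observed - manual) ** 2)))


def test_adding_true_second_seed_decreases_rss(zero_baseline):
    x = np.arange(200)
    y = gaussian(x, 60, 8, 1.0) + gaussian(x, 130, 8, 0.9)
    region = Region("r", 20, 180)
    rss_one = fit_gaussians(y, zero_baseline, region, [60]).rss
    rss_two = fit_gaussians(y, zero_baseline, region, [60, 130]).rss
    assert rss_two < rss_one


def test_seed_outside_region_rejected(zero_baseline):
    y = gaussian(np.arange(101), 50, 5, 1.0)
    with pytest.raises(ValidationError):
        fit_gaussians(y, zero_baseline, Region("r", 40, 60), [70])


def test_region_too_short_for_seed_count(zero_baseline):
    y = gaussian(np.arange(101), 50, 5, 1.0)
    with pytest.raises(ValidationError):
        fit_gaussians(y, zero_baseline, Region("r", 48, 52), [49, 50, 51])


def test_degenerate_peak_flagged_not_dropped(zero_baseline):
    y = gaussian(np.arange(201), 100, 8, 1.0)
    # second seed sits on flat signal: its fitted height collapses
    fit = fit_gaussians(y, zero_baseline, Region("r", 20, 180), [100, 170])
    assert len(fit.peaks) == 2
    assert any(fit.degenerate)


def test_fit_smoothed_switch(zero_baseline):
    y = three_peak_signal(noise_sd=0.02, seed=7)
    seeds = [int(p.mu) for p in THREE_PEAK_TRUTH]
    fit_raw = fit_gaussians(y, zero_baseline, THREE_PEAK_REGION, seeds)
    fit_sm = fit_gaussians(
        y, zero_baseline, THREE_PEAK_REGION, seeds, fit_smoothed=True, smoothing=9
    )
    sm = smooth(y, 9)[THREE_PEAK_REGION.start : THREE_PEAK_REGION.end + 1]
    assert np.allclose(fit_sm.observed, sm)
    assert fit_sm.rss < fit_raw.rss  # smoothing removes noise variance


def test_to_frame_and_summary_report_all_peaks(zero_baseline):
    y = three_peak_signal()
    seeds = [int(p.mu) for p in THREE_PEAK_TRUTH]
    fit = fit_gaussians(y, zero_baseline, THREE_PEAK_REGION, seeds)
    df = fit.to_frame(profile_id="p")
    assert len(df) == 3 and {"mu", "sigma", "height", "area"} <= set(df.columns)
    text = fit.summary()
    assert "peaks: 3" in text and "converged: True" in text
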