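import math

import numpy as np
import pytest

from polyquant import (
    AreaResult,
    Baseline,
    DegenerateInputError,
    Region,
    ValidationError,
    area,
    relative_area,
    results_table,
    summarize,
)


def brute_force_area(y, region, b):
    total = 0.0
    for i in range(region.start, region.end + 1):
        total += float(y[i]) - b
    return total


def test_area_examples():
    b = Baseline("uv", 1.0)
    assert area([1, 2, 3, 4], Region("r", 0, 3), b) == 6.0
    assert area([1.0, 1.0, 1.0, 1.0], Region("r", 1, 3), b) == 0.0


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_area_matches_brute_force(rng):
    for _ in range(50):
        y = rng.normal(size=rng.integers(5, 80))
        s = int(rng.integers(0, len(y) - 1))
        e = int(rng.integers(s, len(y) - 1))
        b = float(rng.normal())
        region = Region("r", s, e)
        assert area(y, region, Baseline("uv", b)) == brute_force_area(y, region, b)


def test_area_region_out_of_range():
    with pytest.raises(ValidationError):
        area([1, 2, 3], Region("r", 0, 3), Baseline("uv", 0.0))


def test_area_channel_mismatch():
    with pytest.raises(ValidationError):
        area([1, 2, 3], Region("r", 0, 2, channel="uv"), Baseline("fluor", 0.0))


def test_negative_area_reported_with_warning():
    with pytest.warns(UserWarning, match="baseline"):
        result = area([1.0, 1.0, 1.0], Region("r", 0, 2), Baseline("uv", 2.0))
    assert result == -3.0  # reported, not clamped


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_split_additivity(rng):
    y = rng.normal(size=40)
    b = Baseline("uv", 0.3)
    whole = area(y, Region("r", 2, 30), b)
    split = area(y, Region("a", 2, 17), b) + area(y, Region("b", 18, 30), b)
    assert abs(whole - split) <= 1e-12 * max(1.0, abs(whole))


def _results_pair(poly, total, pid="p1"):
    return [
        AreaResult(pid, "Polysomes", "uv", 10, 20, 0.0, poly),
        AreaResult(pid, "Total", "uv", 0, 20, 0.0, total),
    ]


def test_relative_area_examples():
    out = relative_area(_results_pair(30.0, 100.0), "Polysomes", "Total")
    rel = [r for r in out if r.relative_to == "Total"]
    assert len(rel) == 1 and rel[0].relative_area == pytest.approx(0.3)
    # numerator == denominator -> exactly 1
    out = relative_area(_results_pair(30.0, 100.0), "Total", "Total")
    assert [r.relative_area for r in out if r.relative_to][0] == 1.0


def test_relative_area_missing_label():
    with pytest.raises(ValidationError):
        relative_area(_results_pair(30.0, 100.0), "Polysomes", "Monosomes")


def test_relative_area_zero_denominator():
    with pytest.raises(DegenerateInputError):
        relative_area(_results_pair(30.0, 0.0), "Polysomes", "Total")


def test_scale_equivariance_of_areas(rng):
    y = rng.normal(loc=3.0, size=30)
    b = Baseline("uv", 0.5)
    f = 2.7
    scaled = 0.5 + f * (y - 0.5)
    for s, e in [(0, 29), (3, 12), (5, 25)]:
        raw = area(y, Region("r", s, e), b)
        assert area(scaled, Region("r", s, e), b) == pytest.approx(f * raw, rel=1e-12)
    # relative areas are invariant under the scaling
    r1 = relative_area(
        _results_pair(area(y, Region("p", 5, 25), b), area(y, Region("t", 0, 29), b)),
        "Polysomes",
        "Total",
    )
    r2 = relative_area(
        _results_pair(
            area(scaled, Region("p", 5, 25), b), area(scaled, Region("t", 0, 29), b)
        ),
        "Polysomes",
        "Total",
    )
    a1 = [r.relative_area for r in r1 if r.relative_to][0]
    a2 = [r.relative_area for r in r2 if r.relative_to][0]
    assert a1 == pytest.approx(a2, rel=1e-12)


def test_summarize_two_point_sd():
    results = [
        AreaResult("p1", "Polysomes", "uv", 0, 5, 0.0, 0.2),
        AreaResult("p2", "Polysomes", "uv", 0, 5, 0.0, 0.4),
    ]
    rows = summarize(results, {"p1": "ctrl", "p2": "ctrl"})
    assert len(rows) == 1
    assert rows[0].mean == pytest.approx(0.3)
    assert rows[0].sd == pytest.approx(math.sqrt(0.02))
    assert rows[0].n == 2


def test_summarize_single_replicate_sd_zero():
    rows = summarize([AreaResult("p1", "Total", "uv", 0, 5, 0.0, 7.0)], {"p1": "c"})
    assert rows[0].mean == 7.0 and rows[0].sd == 0.0 and rows[0].n == 1


def test_summarize_matches_brute_force(rng):
    values = rng.normal(size=3)
    results = [
        AreaResult(f"p{i}", "Total", "uv", 0, 5, 0.0, float(v)) for i, v in enumerate(values)
    ]
    rows = summarize(results, {f"p{i}": "c" for i in range(3)})
    assert rows[0].mean == pytest.approx(float(np.mean(values)))
    assert rows[0].sd == pytest.approx(float(np.std(values, ddof=1)))


def test_summarize_unmapped_profile_rejected():
    with pytest.raises(ValidationError):
        summarize([AreaResult("p1", "Total", "uv", 0, 5, 0.0, 1.0)], {})


def test_results_table_schema():
    df = results_table(_results_pair(30.0, 100.0), {"p1": "ctrl"})
    assert list(df.columns) == [
        "profile_id", "condition", "channel", "region_label", "start", "end",
        "baseline", "raw_area", "relative_to", "relative_area",
    ]
    assert df.shape[0] == 2 and set(df.condition) == {"ctrl"}
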