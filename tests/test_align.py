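import numpy as np
import pytest

from polyquant import (
    AlignmentResult,
    Anchor,
    Baseline,
    DegenerateInputError,
    Profile,
    Region,
    ValidationError,
    align_profiles,
    area,
    normalize_profiles,
    overlay_table,
    remap_index,
    scale_area,
    stretch_length,
)


def _profile(pid, values, fluor=None):
    return Profile(id=pid, uv=np.asarray(values, dtype=float), fluor=fluor)


def test_two_profile_offsets():
    p1, p2 = _profile("a", np.zeros(40)), _profile("b", np.zeros(40))
    result = align_profiles([p1, p2], [Anchor("a", 10), Anchor("b", 25)])
    assert result.offsets == {"a": 15, "b": 0}
    assert result.aligned_x == 25


def test_single_profile_identity():
    result = align_profiles([_profile("a", np.zeros(10))], [Anchor("a", 4)])
    assert result.offsets == {"a": 0} and result.aligned_x == 4


def test_three_profile_anchor_coincidence():
    profiles = [_profile(pid, np.zeros(20)) for pid in "abc"]
    anchors = [Anchor("a", 5), Anchor("b", 7), Anchor("c", 9)]
    result = align_profiles(profiles, anchors)
    assert [result.offsets[p] for p in "abc"] == [4, 2, 0]
    aligned = {a.profile_id: a.index + result.offsets[a.profile_id] for a in anchors}
    assert len(set(aligned.values())) == 1


def test_duplicate_and_missing_anchor_rejected():
    profiles = [_profile("a", np.zeros(10)), _profile("b", np.zeros(10))]
    with pytest.raises(ValidationError):
        align_profiles(profiles, [Anchor("a", 1), Anchor("a", 2)])
    with pytest.raises(ValidationError):
        align_profiles(profiles, [Anchor("a", 1)])


def test_normalization_factors_default_to_one():
    result = AlignmentResult(aligned_x=5, offsets={"a": 0})
    assert result.area_factors["a"] == 1.0 and result.length_factors["a"] == 1.0


def test_scale_area_factor():
    y = np.concatenate([np.full(10, 2.0), np.full(10, 1.0)])  # area over [0,9] = 10 at b=1
    p = _profile("a", y)
    b = Baseline("uv", 1.0)
    scaled, f = scale_area(p, Region("Total", 0, 9), 20.0, b)
    assert f == pytest.approx(2.0)
    assert area(scaled.uv, Region("Total", 0, 9), b) == pytest.approx(20.0, rel=1e-9)


def test_scale_area_identity_when_equal():
    p = _profile("a", np.full(12, 2.0))
    b = Baseline("uv", 1.0)
    own = area(p.uv, Region("Total", 0, 11), b)
    scaled, f = scale_area(p, Region("Total", 0, 11), own, b)
    assert f == 1.0 and np.array_equal(scaled.uv, p.uv)


def test_scale_area_degenerate_total():
    p = _profile("a", np.zeros(10))
    with pytest.raises(DegenerateInputError):
        scale_area(p, Region("Total", 0, 9), 5.0, Baseline("uv", 0.0))


def test_adjust_to_largest_equalizes_totals(rng):
    x = np.arange(60, dtype=float)
    profiles = [
        _profile("a", 0.2 + 1.0 * np.exp(-((x - 30) ** 2) / 50)),
        _profile("b", 0.2 + 2.5 * np.exp(-((x - 30) ** 2) / 50)),
    ]
    b = Baseline("uv", 0.2)
    for p in profiles:
        p.set_baseline(b)
    totals = {"a": Region("Total", 5, 55), "b": Region("Total", 5, 55)}
    out, factors, _, ref = normalize_profiles(profiles, totals, "largest")
    assert ref == "b" and factors["b"] == 1.0
    areas = [area(p.uv, totals[p.id], b) for p in out]
    assert areas[0] == pytest.approx(areas[1], rel=1e-9)


def test_normalize_longest_stretches_to_reference():
    profiles = [_profile("a", np.zeros(30)), _profile("b", np.zeros(60))]
    totals = {"a": Region("Total", 0, 19), "b": Region("Total", 0, 39)}
    out, _, lf, ref = normalize_profiles(profiles, totals, "longest")
    assert ref == "b" and lf["a"] == pytest.approx(2.0)
    assert len(out[0]) == 60 and len(out[1]) == 60


def test_stretch_affine_stays_affine():
    p = _profile("a", [0.0, 1.0, 2.0])
    out = stretch_length(p, 2.0)
    assert len(out) == 6
    assert out.uv[0] == 0.0 and out.uv[-1] == 2.0  # endpoints exact
    assert np.allclose(np.diff(out.uv, 2), 0.0, atol=1e-12)  # still affine


def test_stretch_factor_one_is_identity(rng):
    p = _profile("a", rng.normal(size=15))
    assert np.array_equal(stretch_length(p, 1.0).uv, p.uv)


def test_stretch_then_shrink_restores_affine_trace():
    y = 0.7 + 0.3 * np.arange(21)
    p = _profile("a", y)
    back = stretch_length(stretch_length(p, 2.0), 0.5)
    assert len(back) == 21
    assert np.allclose(back.uv, y, atol=1e-9)


def test_stretch_preserves_monotonicity(rng):
    y = np.cumsum(np.abs(rng.normal(size=25)))
    out = stretch_length(_profile("a", y), 1.7)
    assert np.all(np.diff(out.uv) >= -1e-12)
    assert out.uv.min() >= y.min() - 1e-12 and out.uv.max() <= y.max() + 1e-12


def test_stretch_applies_same_factor_to_fluorescence(rng):
    p = _profile("a", rng.normal(size=20), fluor=rng.normal(size=20))
    out = stretch_length(p, 1.5)
    assert len(out.uv) == len(out.fluor) == 30


def test_stretch_below_minimum_length_rejected():
    with pytest.raises(ValidationError):
        stretch_length(_profile("a", np.zeros(4)), 0.5)


def test_remap_index_endpoints_and_rounding():
    assert remap_index(0, 21, 42) == 0
    assert remap_index(20, 21, 42) == 41
    assert remap_index(10, 21, 41) == 20


def test_overlay_table_is_shifted_and_padded():
    p1 = _profile("a", [1.0, 2.0, 3.0])
    p2 = _profile("b", [4.0, 5.0, 6.0], fluor=[0.1, 0.2, 0.3])
    result = align_profiles([p1, p2], [Anchor("a", 0), Anchor("b", 2)])
    df = overlay_table([p1, p2], result)
    assert list(df.columns) == ["x", "a_uv", "b_uv", "b_fluor"]
    assert np.isnan(df["a_uv"][0]) and df["a_uv"][2] == 1.0  # offset 2
    assert df["b_uv"][0] == 4.0 and df["b_fluor"][2] == 0.3
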