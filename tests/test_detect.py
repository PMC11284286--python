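"""Detection pipeline: elementary operations, frame/segment/plan level."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from bpfqa import (
    CineFrame,
    CineSeries,
    DetectParams,
    ErrorSpec,
    SimConfig,
    assign_frames,
    detect_frame,
    detect_plan,
    inject_errors,
    render_frames,
    segment_fluence,
)
from bpfqa.detect import (
    DetectionError,
    EdgeProfile,
    PeakSet,
    classify_peaks,
    edge_map,
    equalize,
    locate_peaks,
    morph_clean,
    otsu_binarize,
    otsu_threshold,
    pipeline_edges,
    vertical_profile,
)
from bpfqa.plan import expected_positions

# ------------------------------------------------------------- equalize


def test_equalize_preserves_rank(rng):
    img = rng.uniform(0, 100, size=(40, 40))
    eq = equalize(img)
    order = np.argsort(img.ravel(), kind="stable")
    assert np.all(np.diff(eq.ravel()[order]) >= -1e-12)
    assert 0.0 <= eq.min() and eq.max() <= 1.0


def test_equalize_constant_image_warns(caplog):
    img = np.full((8, 8), 3.0)
    with caplog.at_level("WARNING"):
        out = equalize(img)
    np.testing.assert_array_equal(out, img)
    assert "constant" in caplog.text


def test_equalize_rejects_nan():
    with pytest.raises(ValueError):
        equalize(np.array([[np.nan, 1.0]]))


# ------------------------------------------------------------- Otsu


def _brute_force_otsu(img, nbins=256):
    """Independent exhaustive scan of all histogram splits (exact arithmetic)."""
    from fractions import Fraction

    vals = np.asarray(img, dtype=float).ravel()
    counts, edges = np.histogram(vals, bins=nbins, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_k, best_v = 0, Fraction(-1)
    for k in range(nbins - 1):
        w0 = int(counts[: k + 1].sum())
        w1 = int(counts[k + 1 :].sum())
        if w0 == 0 or w1 == 0:
            continue
        m0 = Fraction(int((counts[: k + 1] * np.arange(k + 1)).sum()), w0)
        m1 = Fraction(
            int((counts[k + 1 :] * np.arange(k + 1, nbins)).sum()), w1
        )
        v = Fraction(w0 * w1) * (m0 - m1) ** 2
        if v > best_v:
            best_k, best_v = k, v
    return float(centers[best_k])


def test_otsu_matches_exhaustive_scan(rng):
    for _ in range(5):
        img = np.concatenate(
            [rng.normal(0.2, 0.05, 400), rng.normal(0.8, 0.05, 250)]
        ).reshape(26, 25)
        assert otsu_threshold(img) == _brute_force_otsu(img)


def test_otsu_agrees_with_reference_implementation(rng):
    img = np.concatenate([rng.normal(10, 2, 600), rng.normal(30, 2, 400)])
    bin_width = (img.max() - img.min()) / 256
    assert abs(otsu_threshold(img) - skimage_otsu(img, nbins=256)) <= bin_width


def test_otsu_separates_two_levels():
    img = np.array([0.0] * 30 + [10.0] * 20).reshape(5, 10)
    t = otsu_threshold(img)
    assert 0.0 < t < 10.0
    mask = otsu_binarize(img)
    assert mask.sum() == 20


def test_otsu_constant_image_raises():
    with pytest.raises(ValueError, match="constant"):
        otsu_threshold(np.ones((4, 4)))


# ------------------------------------------------------------- morphology / edges


def test_morph_clean_idempotent_on_clean_mask():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 4:16] = True
    np.testing.assert_array_equal(morph_clean(mask, 1), mask)


def test_morph_clean_fills_small_holes():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 4:16] = True
    holed = mask.copy()
    holed[9, 9] = False
    np.testing.assert_array_equal(morph_clean(holed, 1), mask)


def test_morph_clean_preserves_border_regions():
    mask = np.zeros((10, 10), bool)
    mask[:, :4] = True
    np.testing.assert_array_equal(morph_clean(mask, 1), mask)


def test_edge_map_locates_rectangle_boundary():
    mask = np.zeros((40, 60), bool)
    mask[5:35, 10:50] = True
    edges = edge_map(mask)
    cols = np.nonzero(edges.any(axis=0))[0]
    assert abs(cols.min() - 10) <= 1
    assert abs(cols.max() - 49) <= 1


def test_edge_map_uniform_masks_have_no_edges():
    assert not edge_map(np.ones((8, 8), bool)).any()
    assert not edge_map(np.zeros((8, 8), bool)).any()


def test_vertical_profile_counts_and_coordinates():
    edges = np.zeros((5, 7), bool)
    edges[:, 2] = True
    edges[1, 4] = True
    profile = vertical_profile(edges, pitch_mm=0.5)
    assert profile.values.sum() == edges.sum()
    assert profile.values[2] == 5
    np.testing.assert_allclose(profile.x_mm, (np.arange(7) - 3.0) * 0.5)


def test_vertical_profile_requires_coordinates():
    with pytest.raises(ValueError):
        vertical_profile(np.zeros((3, 3), bool))


# ------------------------------------------------------------- peaks


def test_locate_peaks_subpixel_parabola():
    values = np.zeros(21)
    values[[9, 10, 11]] = [1.0, 2.0, 1.5]
    profile = EdgeProfile(values=values, x_mm=(np.arange(21) - 10.0) * 1.0)
    peaks = locate_peaks(profile, min_separation_mm=3.0)
    assert len(peaks) == 1
    # dx = 0.5 (v[-1] - v[+1]) / (v[-1] - 2 v[0] + v[+1]) = 1/6
    assert peaks[0][0] == pytest.approx(1.0 / 6.0, abs=1e-9)
    assert peaks[0][1] == 2.0


def test_locate_peaks_symmetric_peak_is_exact():
    values = np.zeros(21)
    values[[9, 10, 11]] = [1.0, 2.0, 1.0]
    profile = EdgeProfile(values=values, x_mm=(np.arange(21) - 10.0) * 1.0)
    assert locate_peaks(profile)[0][0] == pytest.approx(0.0, abs=1e-12)


def test_locate_peaks_min_separation():
    values = np.zeros(30)
    values[10] = 5.0
    values[12] = 4.0
    profile = EdgeProfile(values=values, x_mm=np.arange(30) * 1.0)
    peaks = locate_peaks(profile, min_separation_mm=5.0)
    assert len(peaks) == 1
    assert peaks[0][1] == 5.0


def test_locate_peaks_empty_profile():
    profile = EdgeProfile(values=np.zeros(10), x_mm=np.arange(10.0))
    assert locate_peaks(profile) == []


def test_classify_peaks_roles():
    peaks = [(-76.0, 100.0), (-70.0, 50.0), (70.0, 50.0), (74.0, 100.0)]
    expected = {"x1": -76.2, "x2": 74.1, "slit_centers": [-70.0, 70.0]}
    out = classify_peaks(peaks, expected, capture_mm=3.0, image_height=100.0)
    assert out.roles == ["x1_jaw", "aperture_edge", "aperture_edge", "x2_jaw"]
    assert out.position("x1_jaw") == -76.0
    assert out.position("x2_jaw") == 74.0


def test_classify_peaks_prefers_full_height():
    # a half-height aperture peak sits closer to the expectation than the jaw
    peaks = [(-75.5, 40.0), (-74.5, 100.0), (70.0, 100.0)]
    out = classify_peaks(
        peaks, {"x1": -75.6, "x2": 70.0}, capture_mm=3.0, image_height=100.0
    )
    assert out.position("x1_jaw") == -74.5


def test_classify_peaks_missing_jaw_raises():
    with pytest.raises(DetectionError, match="x2_jaw"):
        classify_peaks([(-76.0, 100.0)], {"x1": -76.0, "x2": 74.0}, capture_mm=3.0)


def test_peakset_validation():
    with pytest.raises(ValueError, match="increasing"):
        PeakSet(positions=[1.0, 1.0], heights=[1.0, 1.0], roles=["a", "b"])
    with pytest.raises(ValueError, match="more than once"):
        PeakSet(
            positions=[0.0, 1.0], heights=[1.0, 1.0], roles=["x1_jaw", "x1_jaw"]
        )


# ------------------------------------------------------------- pipeline


def test_pipeline_edges_on_binary_contrast_image():
    pitch = 0.336
    n = 400
    x = (np.arange(n) - (n - 1) / 2.0) * pitch
    img = np.where((x >= -30.0) & (x <= 25.0), 1.0, 0.0)[None, :].repeat(120, axis=0)
    peaks = pipeline_edges(img, x)
    jaw_like = [p for p in peaks if p[1] > 60]
    assert len(jaw_like) == 2
    assert jaw_like[0][0] == pytest.approx(-30.0, abs=pitch)
    assert jaw_like[1][0] == pytest.approx(25.0, abs=pitch)


# ------------------------------------------------------------- frame / plan level


def _first_frame(series: CineSeries, segment: int) -> CineFrame:
    return next(f for f in series.frames if f.segment_label == segment)


def test_detect_frame_noise_free(clean_series, plan, machine):
    expected = expected_positions(plan)
    for seg_idx in (1, 5):
        exp = expected.iloc[seg_idx - 1].to_dict()
        det = detect_frame(_first_frame(clean_series, seg_idx), exp, machine)
        assert det.x1 == pytest.approx(exp["x1"], abs=0.1)
        assert det.x2 == pytest.approx(exp["x2"], abs=0.1)
        roles = det.peaks.roles
        assert "x1_jaw" in roles and "x2_jaw" in roles


def test_detect_frame_intensity_scale_invariant(clean_series, plan, machine):
    exp = expected_positions(plan).iloc[0].to_dict()
    frame = _first_frame(clean_series, 1)
    scaled = CineFrame(
        pixels=frame.pixels * 7.3, pitch_mm=frame.pitch_mm, frame_index=0
    )
    a = detect_frame(frame, exp, machine)
    b = detect_frame(scaled, exp, machine)
    assert b.x1 == pytest.approx(a.x1, abs=1e-6)
    assert b.x2 == pytest.approx(a.x2, abs=1e-6)


@pytest.mark.parametrize("dx1,dx2", [(0.5, -0.5), (-1.0, 1.0)])
def test_detect_frame_linear_in_injected_offset(plan, machine, dx1, dx2):
    """Noise-free oracle: injected jaw offsets shift detections linearly."""
    sim = SimConfig(noise_rel=0.0, frames_per_segment=1)
    err = inject_errors(plan, ErrorSpec(jaw_offsets={1: (dx1, dx2)}))
    base_f = render_frames(segment_fluence(plan.segments[0], machine, sim), sim)[0]
    err_f = render_frames(segment_fluence(err.segments[0], machine, sim), sim)[0]
    exp0 = expected_positions(plan).iloc[0].to_dict()
    exp1 = expected_positions(err).iloc[0].to_dict()
    det0 = detect_frame(base_f, exp0, machine)
    det1 = detect_frame(err_f, exp1, machine)
    assert det1.x1 - det0.x1 == pytest.approx(dx1, abs=0.2)
    assert det1.x2 - det0.x2 == pytest.approx(dx2, abs=0.2)
    assert det1.x1 == pytest.approx(exp1["x1"], abs=0.2)
    assert det1.x2 == pytest.approx(exp1["x2"], abs=0.2)


def test_assign_frames_recovers_labels(noisy_series, plan):
    stripped = CineSeries(
        frames=[
            CineFrame(
                pixels=f.pixels, pitch_mm=f.pitch_mm, frame_index=f.frame_index
            )
            for f in noisy_series.frames
        ],
        machine=noisy_series.machine,
    )
    labeled = assign_frames(stripped, plan)
    assert len(labeled) == len(noisy_series)
    for orig, new in zip(noisy_series.frames, labeled.frames):
        assert new.segment_label == orig.segment_label


def test_assign_frames_missing_segment_raises(noisy_series, plan):
    frames = [
        CineFrame(pixels=f.pixels, pitch_mm=f.pitch_mm, frame_index=f.frame_index)
        for f in noisy_series.frames
        if f.segment_label != 3
    ]
    with pytest.raises(DetectionError, match="segment 3"):
        assign_frames(CineSeries(frames=frames), plan)


def test_detect_plan_noise_free(clean_series, plan):
    result = detect_plan(clean_series, plan)
    assert np.all(result.table["diff"].abs() <= 0.1)


@pytest.fixture(scope="module")
def noisy_result(noisy_series, plan):
    return detect_plan(noisy_series, plan)


def test_detect_plan_accuracy_under_noise(noisy_result):
    assert noisy_result.mean_abs_diff <= 0.5
    assert np.all(noisy_result.table["diff"].abs() <= 0.5)


def test_detect_plan_frame_spread(noisy_result):
    sd = noisy_result.table["sd"]
    assert np.all(sd >= 0.0)
    assert np.all(sd < 0.4)
    assert sd.max() > 0.0  # noisy frames cannot agree exactly


def test_detect_plan_table_layout(noisy_result):
    table = noisy_result.table
    assert set(table["jaw"]) == {"X1", "X2"}
    assert len(table) == 16
    wide = noisy_result.to_wide()
    assert list(wide["segment"]) == list(range(1, 9))
    assert "X1_diff" in wide.columns and "X2_detected" in wide.columns
    np.testing.assert_allclose(
        wide["X1_planned"] - wide["X1_detected"], wide["X1_diff"], atol=1e-12
    )


def test_detect_plan_wrong_expectation_raises(clean_series, plan):
    shifted = inject_errors(
        plan, ErrorSpec(jaw_offsets={i: (-20.0, 20.0) for i in range(1, 9)})
    )
    with pytest.raises(DetectionError):
        detect_plan(clean_series, shifted)


# ------------------------------------------------------------- properties


@given(st.integers(0, 2**31 - 1))
def test_locate_peaks_positions_sorted_and_within_range(seed):
    r = np.random.default_rng(seed)
    values = np.clip(r.normal(1.0, 1.0, size=50), 0.0, None)
    profile = EdgeProfile(values=values, x_mm=np.arange(50) * 0.5)
    peaks = locate_peaks(profile, min_separation_mm=1.0)
    pos = [p[0] for p in peaks]
    assert pos == sorted(pos)
    for p, _ in peaks:
        assert profile.x_mm[0] - 0.25 <= p <= profile.x_mm[-1] + 0.25
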