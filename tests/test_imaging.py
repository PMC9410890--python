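"""Segmentation, tracking and death calling must recover the planted ground
truth, and the CV statistic must follow its exact definition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctasurv.exceptions import UndefinedCVError
from punctasurv.imaging import (
    ROI,
    DeathParams,
    SegmentationParams,
    Track,
    call_death,
    compute_cv,
    link_tracks,
    segment_frame,
    subtract_background,
)


# ---------------------------------------------------------------------------
# background subtraction


def test_background_subtraction_on_fixtures():
    const = np.full((20, 20), 7.0)
    assert np.array_equal(subtract_background(const), np.zeros((20, 20)))
    assert np.array_equal(subtract_background(np.zeros((5, 5))), np.zeros((5, 5)))
    # disc occupying <50% of pixels on flat background b: median = b exactly
    frame = np.full((30, 30), 10.0)
    frame[5:10, 5:10] += 40.0
    out = subtract_background(frame)
    assert np.array_equal(out[5:10, 5:10], np.full((5, 5), 40.0))
    assert np.all(out[15:, 15:] == 0.0)


# ---------------------------------------------------------------------------
# coefficient of variation


@pytest.mark.parametrize(
    "values, expected",
    [
        ([7.0] * 5, 0.0),
        ([1.0, 3.0], 0.5),  # mean 2, population sd 1
        ([0.0, 0.0, 0.0, 12.0], math.sqrt(3.0)),  # mean 3, sd sqrt(27)
    ],
)
def test_cv_hand_fixtures(values, expected):
    assert compute_cv(np.array(values)) == pytest.approx(expected, abs=1e-12)


def test_cv_errors():
    with pytest.raises(UndefinedCVError):
        compute_cv(np.array([5.0]))
    with pytest.raises(UndefinedCVError):
        compute_cv(np.array([0.0, 0.0]))
    with pytest.raises(UndefinedCVError):
        compute_cv(np.array([-2.0, 1.0]))


@settings(deadline=None, max_examples=50)
@given(
    values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=30),
    gain=st.floats(1e-3, 1e3),
)
def test_cv_is_gain_invariant_and_zero_iff_uniform(values, gain):
    arr = np.array(values)
    cv = compute_cv(arr)
    assert compute_cv(arr * gain) == pytest.approx(cv, rel=1e-9)
    if np.all(arr == arr[0]):
        assert cv == 0.0
    else:
        assert cv > 0.0


# ---------------------------------------------------------------------------
# segmentation


def _disc_frame(centers, radius=6.0, level=60.0, bg=20.0, shape=(128, 128), seed=0):
    rng = np.random.default_rng(seed)
    frame = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        frame[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] += level
    noisy = rng.poisson(frame + bg).astype(float)
    return subtract_background(noisy)


def test_blank_noise_frame_yields_no_rois():
    rng = np.random.default_rng(1)
    frame = subtract_background(rng.poisson(20.0, (128, 128)).astype(float))
    assert segment_frame(frame, frame) == []
    zero = np.zeros((64, 64))
    assert segment_frame(zero, zero) == []


def test_planted_somata_recovered_with_accurate_centroids():
    centers = [(30, 30), (30, 95), (95, 40), (90, 100)]
    frame = _disc_frame(centers)
    rois = segment_frame(frame, frame)
    assert len(rois) == len(centers)
    found = sorted(r.centroid for r in rois)
    for (fy, fx), (cy, cx) in zip(found, sorted((float(a), float(b)) for a, b in centers)):
        assert math.hypot(fy - cy, fx - cx) < 2.0


def test_touching_discs_merge_into_one_roi():
    frame = _disc_frame([(60, 58), (60, 70)])  # 12 px apart, radius 6 => touching
    rois = segment_frame(frame, frame)
    assert len(rois) == 1
    assert rois[0].area > 150


def test_roi_statistics_measured_on_reporter_channel():
    trk = _disc_frame([(40, 40)])
    rep = np.zeros_like(trk)
    rep[38:43, 38:43] = 50.0
    (roi,) = segment_frame(trk, rep)
    inside = rep[roi.coords[:, 0], roi.coords[:, 1]]
    assert roi.mean == pytest.approx(inside.mean())
    assert roi.sd == pytest.approx(inside.std(ddof=0))
    assert roi.cv == pytest.approx(inside.std(ddof=0) / inside.mean())


# ---------------------------------------------------------------------------
# linking


def _roi(rid, t, cy, cx, tracking_mean=60.0):
    return ROI(
        roi_id=rid,
        timepoint=t,
        coords=np.array([[int(cy), int(cx)]]),
        centroid=(cy, cx),
        area=100,
        mean=50.0,
        sd=10.0,
        cv=0.2,
        tracking_mean=tracking_mean,
    )


def test_static_roi_links_into_single_full_track():
    frames = [[_roi(0, t, 50.0, 50.0)] for t in range(10)]
    (track,) = link_tracks(frames)
    assert len(track.rois) == 10
    assert track.first_timepoint == 0


def test_no_identity_swaps_for_well_separated_neurons():
    rng = np.random.default_rng(3)
    a, b = np.array([30.0, 30.0]), np.array([90.0, 90.0])
    frames = []
    for t in range(10):
        a = a + rng.normal(0, 2, 2)
        b = b + rng.normal(0, 2, 2)
        frames.append([_roi(0, t, *a), _roi(1, t, *b)])
    tracks = link_tracks(frames)
    assert len(tracks) == 2
    for tr, start in zip(tracks, ([30, 30], [90, 90])):
        assert len(tr.rois) == 10
        # every ROI stays near its own start; never jumps to the other neuron
        for roi in tr.rois:
            assert math.hypot(roi.centroid[0] - start[0], roi.centroid[1] - start[1]) < 30


def test_late_appearing_rois_start_no_track():
    frames = [[_roi(0, 0, 50.0, 50.0)]] + [
        [_roi(0, t, 50.0, 50.0), _roi(1, t, 100.0, 100.0)] for t in range(1, 5)
    ]
    tracks = link_tracks(frames)
    assert len(tracks) == 1


def test_tracks_have_one_roi_per_timepoint_and_are_contiguous(tracked_cohort):
    for tr, _ in tracked_cohort["pairs"]:
        tps = [roi.timepoint for roi in tr.rois]
        assert tps == list(range(tr.first_timepoint, tr.first_timepoint + len(tps)))


def test_cohort_tracking_recovers_nearly_all_neurons(tracked_cohort):
    truth = tracked_cohort["truth"]
    visible = truth[truth["death_interval"].isna() | (truth["death_interval"] > 1)]
    assert len(tracked_cohort["pairs"]) >= 0.99 * len(visible)


# ---------------------------------------------------------------------------
# death calling


def test_absent_roi_sets_death_interval():
    track = Track(neuron_id=0, rois=[_roi(0, t, 50.0, 50.0) for t in range(5)])
    out = call_death(track, n_timepoints=10)
    assert out.death_interval == 6 and not out.censored


def test_tracking_intensity_collapse_sets_death_interval():
    rois = [_roi(0, t, 50.0, 50.0) for t in range(10)]
    for t in range(3, 10):
        rois[t].tracking_mean = 5.0  # < 0.2 * 60
    out = call_death(Track(neuron_id=0, rois=rois), n_timepoints=10)
    assert out.death_interval == 4


def test_survivor_is_censored_at_last_timepoint():
    track = Track(neuron_id=0, rois=[_roi(0, t, 50.0, 50.0) for t in range(10)])
    out = call_death(track, n_timepoints=10)
    assert out.censored and out.death_interval is None


def test_track_missing_first_timepoint_is_rejected():
    track = Track(neuron_id=0, rois=[_roi(0, 3, 50.0, 50.0)], first_timepoint=3)
    with pytest.raises(ValueError, match="timepoint-1"):
        call_death(track, n_timepoints=10)


def test_cohort_death_intervals_match_ground_truth(tracked_cohort):
    ok = total = 0
    for tr, row in tracked_cohort["pairs"]:
        total += 1
        true_di = row["death_interval"]
        if np.isnan(true_di):
            ok += tr.censored
        else:
            ok += (not tr.censored) and tr.death_interval == true_di
    assert total > 0
    assert ok / total >= 0.98
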