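"""Trace linking, the four exclusion rules, and dwell extraction."""

import numpy as np
import pytest

from dwellscope import (
    Detection,
    DetectionParams,
    MovieSimParams,
    TrackingParams,
    extract_dwells,
    filter_traces,
    link_traces,
    pool_dwells,
    simulate_movie,
)
from dwellscope.detection import detect_frame

from tests._oracles import brute_force_kept_events


def det(frame, x, y):
    return Detection(frame=frame, x_px=float(x), y_px=float(y), amplitude=100.0,
                     sigma_x_px=1.3, sigma_y_px=1.3, offset=0.0, fit_ok=True)


PARAMS = TrackingParams()


def test_stationary_punctum_single_trace():
    dets = [det(f, 10.0, 10.0) for f in range(5)]
    traces = link_traces(dets, PARAMS, n_frames=10)
    assert len(traces) == 1
    assert traces[0].dwell_frames == 5
    assert traces[0].n_gaps_bridged == 0


@pytest.mark.parametrize(
    "frames,expected_traces,expected_dwell",
    [
        ([0, 1, 2, 7, 8, 9], 2, None),        # 4-frame gap exceeds tolerance
        ([0, 1, 2, 6, 7, 8, 9], 1, 10),       # 3-frame gap bridged
    ],
)
def test_gap_tolerance(frames, expected_traces, expected_dwell):
    dets = [det(f, 20.0, 20.0) for f in frames]
    traces = link_traces(dets, PARAMS, n_frames=12)
    assert len(traces) == expected_traces
    if expected_traces == 1:
        assert traces[0].dwell_frames == expected_dwell
        assert traces[0].n_gaps_bridged == 10 - len(frames)


def test_detections_out_of_order_rejected():
    with pytest.raises(ValueError, match="sorted"):
        link_traces([det(3, 1, 1), det(1, 1, 1)], PARAMS, n_frames=5)


def test_equidistant_tie_broken_deterministically():
    """Two detections equidistant from an open trace: the lower detection
    index wins, reproducibly."""
    dets0 = [det(0, 10.0, 10.0)]
    frame1 = [det(1, 11.0, 10.0), det(1, 9.0, 10.0)]
    for _ in range(3):
        traces = link_traces(dets0 + frame1, PARAMS, n_frames=3)
        joined = [t for t in traces if t.first_frame == 0][0]
        assert joined.detections[1] is frame1[0]


def test_every_detection_in_exactly_one_trace():
    p = MovieSimParams(field_w_px=64, field_h_px=64, pixel_size_um=0.2, n_frames=80,
                       tau_true_s=6.0, arrival_rate_per_um2_s=0.02, amp_mean=400.0, seed=21)
    mv = simulate_movie(p)
    dets = []
    for f in range(mv.n_frames):
        dets.extend(detect_frame(mv.stack[f], DetectionParams(), f))
    traces = link_traces(dets, PARAMS, mv.n_frames)
    ids = [id(d) for t in traces for d in t.detections]
    assert len(ids) == len(dets)
    assert len(set(ids)) == len(ids)


def _trace_at(frames, x, y, params=PARAMS, n_frames=100):
    return link_traces([det(f, x, y) for f in frames], params, n_frames)[0]


def test_boundary_and_single_frame_rules():
    traces = link_traces(
        [det(0, 5, 5), det(1, 5, 5)]            # starts on frame 0
        + [det(50, 30, 30)]                      # single frame
        + [det(97, 50, 50), det(98, 50, 50), det(99, 50, 50)],  # ends on last
        PARAMS, n_frames=100,
    )
    filter_traces(traces, PARAMS, 100, pixel_size_um=0.065)
    reasons = {(t.first_frame): t.reason for t in traces}
    assert reasons[0] == "boundary"
    assert reasons[50] == "single_frame"
    assert reasons[97] == "boundary"


def test_concurrent_proximity_both_removed_at_0p8um_kept_at_1p2um():
    """At 0.065 um/px, 0.8 um = 12.3 px (both removed) and 1.2 um = 18.5 px
    (both kept)."""
    for sep_um, removed in [(0.8, True), (1.2, False)]:
        sep_px = sep_um / 0.065
        dets = (
            [det(f, 30.0, 30.0) for f in range(10, 20)]
            + [det(f, 30.0 + sep_px, 30.0) for f in range(12, 22)]
        )
        dets.sort(key=lambda d: d.frame)
        traces = link_traces(dets, PARAMS, 100)
        filter_traces(traces, PARAMS, 100, pixel_size_um=0.065)
        assert len(traces) == 2
        if removed:
            assert all(t.reason == "concurrent_proximity" for t in traces)
        else:
            assert all(t.status == "kept" for t in traces)


def test_repeated_site_all_removed():
    dets = (
        [det(f, 40.0, 40.0) for f in range(5, 10)]
        + [det(f, 40.5, 40.0) for f in range(60, 66)]
    )
    traces = link_traces(dets, PARAMS, 100)
    assert len(traces) == 2
    filter_traces(traces, PARAMS, 100, pixel_size_um=0.065)
    assert all(t.reason == "repeated_site" for t in traces)


def test_kept_traces_satisfy_all_predicates_and_order_independence():
    p = MovieSimParams(field_w_px=96, field_h_px=96, pixel_size_um=0.2, n_frames=120,
                       tau_true_s=8.0, arrival_rate_per_um2_s=0.01, amp_mean=400.0, seed=3)
    mv = simulate_movie(p)
    dets = []
    for f in range(mv.n_frames):
        dets.extend(detect_frame(mv.stack[f], DetectionParams(), f))
    traces = link_traces(dets, PARAMS, mv.n_frames)
    filter_traces(traces, PARAMS, mv.n_frames, mv.pixel_size_um)
    excl_px = 1.0 / mv.pixel_size_um
    kept = [t for t in traces if t.status == "kept"]
    assert kept  # non-degenerate scenario
    for t in kept:
        assert t.first_frame > 0 and t.last_frame < mv.n_frames - 1
        assert t.first_frame != t.last_frame
        for o in traces:
            if o is t:
                continue
            dist = np.hypot(t.centroid_x_px - o.centroid_x_px, t.centroid_y_px - o.centroid_y_px)
            overlap = t.first_frame <= o.last_frame and o.first_frame <= t.last_frame
            assert not (overlap and dist < excl_px)
            assert not ((not overlap) and dist <= PARAMS.same_site_radius_px)
    # the kept set does not depend on the order the traces are presented in
    shuffled = list(traces)
    np.random.default_rng(0).shuffle(shuffled)
    for t in shuffled:
        t.status, t.reason = "open", None
    filter_traces(shuffled, PARAMS, mv.n_frames, mv.pixel_size_um)
    assert {t.trace_id for t in shuffled if t.status == "kept"} == {t.trace_id for t in kept}


@pytest.mark.parametrize("frames,dt,expected", [((10, 19), 1.0, 10.0), ((3, 7), 2.0, 10.0)])
def test_dwell_arithmetic(frames, dt, expected):
    dets = [det(f, 10, 10) for f in range(frames[0], frames[1] + 1)]
    traces = link_traces(dets, PARAMS, 50)
    filter_traces(traces, PARAMS, 50, 0.065)
    dw = extract_dwells(traces, dt)
    assert list(dw.dwell_s) == [expected]


def test_gap_frames_counted_or_not():
    dets = [det(f, 10, 10) for f in (5, 6, 9, 10)]  # 2-frame gap bridged
    traces = link_traces(dets, PARAMS, 20)
    filter_traces(traces, PARAMS, 20, 0.065)
    assert extract_dwells(traces, 1.0).dwell_s[0] == 6.0
    assert extract_dwells(traces, 1.0, include_gap_frames=False).dwell_s[0] == 4.0


def test_empty_dwellset_warns_and_pooling():
    traces = link_traces([det(0, 5, 5), det(1, 5, 5)], PARAMS, 10)
    filter_traces(traces, PARAMS, 10, 0.065)  # boundary-removed
    with pytest.warns(UserWarning, match="no kept traces"):
        empty = extract_dwells(traces, 1.0)
    assert len(empty) == 0

    t1 = link_traces([det(f, 10, 10) for f in (2, 3, 4)], PARAMS, 10)
    filter_traces(t1, PARAMS, 10, 0.065)
    d1 = extract_dwells(t1, 1.0, movie_id="a")
    d2 = extract_dwells(t1, 1.0, movie_id="b")
    pooled = pool_dwells([d1, d2])
    assert len(pooled) == 2
    assert set(pooled.table["movie_id"]) == {"a", "b"}


def test_kept_traces_match_truth_enumeration_on_a_movie():
    """Pipeline kept-trace set equals the brute-force rule evaluation on the
    ground-truth table, exactly, at high SNR."""
    p = MovieSimParams(field_w_px=160, field_h_px=160, pixel_size_um=0.065,
                       n_frames=150, tau_true_s=8.0,
                       arrival_rate_per_um2_s=9e-4, amp_mean=1000.0, amp_sd=30.0,
                       border_margin_px=8.0, seed=42)
    mv = simulate_movie(p)
    dparams = DetectionParams(log_threshold=0.3)  # sparse, high-SNR regime
    dets = []
    for f in range(mv.n_frames):
        dets.extend(detect_frame(mv.stack[f], dparams, f))
    traces = link_traces(dets, PARAMS, mv.n_frames)
    filter_traces(traces, PARAMS, mv.n_frames, mv.pixel_size_um)
    kept = [t for t in traces if t.status == "kept"]
    oracle = brute_force_kept_events(mv.truth, mv.n_frames, 1.0, p.pixel_size_um,
                                     PARAMS.exclusion_radius_um, PARAMS.same_site_radius_px)
    assert len(kept) == len(oracle) > 0
    for first, last, x, y in oracle:
        match = [
            t for t in kept
            if t.first_frame == first and t.last_frame == last
            and np.hypot(t.centroid_x_px - x, t.centroid_y_px - y) < 0.5
        ]
        assert len(match) == 1
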