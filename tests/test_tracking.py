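"""Linking, motion classification, state hysteresis, event statistics."""

import itertools

import numpy as np
import pytest

from erestrack.config import EventParams, TrackingParams
from erestrack.tracking import (
    Event,
    Track,
    classify_motion,
    event_frequency,
    link_tracks,
    state_series,
)


def _track(track_id, positions, kind="eres", frames=None):
    tr = Track(track_id=track_id, kind=kind)
    frames = frames if frames is not None else range(len(positions))
    for f, xy in zip(frames, positions):
        tr.frames.append(int(f))
        tr.xy_nm.append(np.asarray(xy, dtype=float))
    return tr


# ---------------------------------------------------------------------------
# link_tracks


def test_two_stationary_points():
    dets = {t: np.array([[0.0, 0.0], [5000.0, 0.0]]) for t in range(3)}
    tracks = link_tracks(dets)
    assert len(tracks) == 2
    assert all(len(tr) == 3 for tr in tracks)


def test_crossing_assignment_matches_brute_force():
    # two points crossing; optimal pairing minimizes summed displacement
    prev = np.array([[0.0, 0.0], [300.0, 0.0]])
    cur = np.array([[80.0, 0.0], [260.0, 0.0]])
    tracks = link_tracks({0: prev, 1: cur})
    ends = sorted(
        (tuple(tr.xy_nm[0]), tuple(tr.xy_nm[-1])) for tr in tracks
    )
    # brute force over both pairings
    best = min(
        itertools.permutations(range(2)),
        key=lambda p: sum(
            np.linalg.norm(cur[p[i]] - prev[i]) for i in range(2)
        ),
    )
    expected = sorted(
        ((tuple(prev[i]), tuple(cur[best[i]])) for i in range(2))
    )
    assert ends == expected


def test_gap_closing():
    dets = {
        0: np.array([[0.0, 0.0]]),
        1: np.empty((0, 2)),
        2: np.array([[100.0, 0.0]]),
    }
    tracks = link_tracks(dets, TrackingParams(max_disp_nm=400, max_gap=1))
    assert len(tracks) == 1
    assert tracks[0].frames == [0, 2]


def test_no_gap_closing_beyond_max_gap():
    dets = {
        0: np.array([[0.0, 0.0]]),
        1: np.empty((0, 2)),
        2: np.empty((0, 2)),
        3: np.array([[100.0, 0.0]]),
    }
    tracks = link_tracks(dets, TrackingParams(max_disp_nm=400, max_gap=1))
    assert len(tracks) == 2


def test_displacement_gate():
    dets = {0: np.array([[0.0, 0.0]]), 1: np.array([[2000.0, 0.0]])}
    tracks = link_tracks(dets, TrackingParams(max_disp_nm=400))
    assert len(tracks) == 2


def test_generator_track_recovery():
    from erestrack.config import RunConfig, SceneConfig
    from erestrack.pipeline import run_pipeline, validate_against_truth
    from erestrack.simulate import simulate_scene

    scene = SceneConfig(
        field_size_px=(320, 320), n_golgi=2, n_puncta=14, frac_bound=0.5,
        n_frames=30, cytoskeleton_inhibited=True, seed=13,
        channels=("eres", "golgi"),
    )
    truth, ren = simulate_scene(scene)
    res = run_pipeline(RunConfig(scene=scene), renderer=ren)
    metrics = validate_against_truth(res)
    assert metrics["track_recovery"] >= 0.9


# ---------------------------------------------------------------------------
# classify_motion


def test_linear_track_directional():
    positions = [(1000.0 * t * 0.1, 0.0) for t in range(20)]
    m = classify_motion(_track(0, positions), 0.1)
    assert m.label == "directional"
    assert m.straightness == pytest.approx(1.0)
    assert m.mean_speed_nm_s == pytest.approx(1000.0)


def test_short_track_undefined():
    m = classify_motion(_track(0, [(0, 0)] * 5), 0.1)
    assert m.label == "undefined"


def test_brownian_tracks_random_over_replicates():
    # D = 1e4 nm^2/s, 100 steps: P(random) >= 0.95 over replicate tracks
    rng = np.random.default_rng(29)
    sd = np.sqrt(2 * 1e4 * 0.1)
    n_random = 0
    reps = 1000
    for _ in range(reps):
        steps = rng.normal(0, sd, size=(100, 2))
        positions = np.cumsum(steps, axis=0)
        if classify_motion(_track(0, positions), 0.1).label == "random":
            n_random += 1
    assert n_random / reps >= 0.95


# ---------------------------------------------------------------------------
# state_series


def _golgi_track(xy=(0.0, 0.0), n=10, track_id=1000):
    return _track(track_id, [xy] * n, kind="golgi")


def _eres_from_states(states, near=(0.0, 0.0), far=(5000.0, 5000.0)):
    return _track(0, [near if s == "B" else far for s in states])


def test_state_series_capture_release():
    g = _golgi_track(n=8)
    tr = _eres_from_states("FFBBBBFF")
    ss = state_series(tr, [g], EventParams(min_dwell_frames=2), 0.1)
    kinds = [(e.kind, e.frame) for e in ss.events]
    assert kinds == [("capture", 2), ("release", 6)]


def test_one_frame_flicker_suppressed():
    g = _golgi_track(n=4)
    tr = _eres_from_states("FBFF")
    ss = state_series(tr, [g], EventParams(min_dwell_frames=2), 0.1)
    assert ss.events == []
    assert np.all(ss.state == -1)


def test_release_then_capture_by_second_golgi():
    g1 = _golgi_track((0.0, 0.0), n=6, track_id=1000)
    g2 = _golgi_track((10000.0, 0.0), n=6, track_id=1001)
    positions = [(0, 0), (0, 0), (5000, 5000), (5000, 5000), (10000, 0), (10000, 0)]
    tr = _track(0, positions)
    ss = state_series(tr, [g1, g2], EventParams(min_dwell_frames=2), 0.1)
    kinds = [(e.kind, e.golgi_track_id) for e in ss.events]
    assert kinds == [("release", 1000), ("capture", 1001)]


def test_dwell_filter_hand_enumeration():
    # exhaustive check of the dwell rule on all length-6 binary state strings
    from erestrack.tracking import _dwell_filter

    def oracle(states, min_dwell):
        current = states[0]
        out = []
        runs = []
        i = 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            runs.append((states[i], j - i))
            i = j
        for s, length in runs:
            if s != current and length >= min_dwell:
                current = s
            out.extend([current] * length)
        return out

    for bits in itertools.product([0, -1], repeat=6):
        arr = np.array(bits)
        for dwell in (1, 2, 3):
            got = list(_dwell_filter(arr, dwell))
            assert got == oracle(list(bits), dwell), (bits, dwell)


def test_increasing_dwell_never_increases_events():
    rng = np.random.default_rng(31)
    g = _golgi_track(n=40)
    states = "".join(rng.choice(["F", "B"], size=40))
    tr = _eres_from_states(states)
    counts = []
    for dwell in (1, 2, 3, 5, 8):
        ss = state_series(tr, [g], EventParams(min_dwell_frames=dwell), 0.1)
        counts.append(len(ss.events))
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_capture_release_balance_invariant():
    # per (eres, golgi) pair: #captures - #releases in {-1, 0, 1}
    rng = np.random.default_rng(37)
    g = _golgi_track(n=60)
    for _ in range(50):
        states = "".join(rng.choice(["F", "B"], size=60))
        tr = _eres_from_states(states)
        ss = state_series(tr, [g], EventParams(min_dwell_frames=2), 0.1)
        n_cap = sum(e.kind == "capture" for e in ss.events)
        n_rel = sum(e.kind == "release" for e in ss.events)
        assert n_cap - n_rel in (-1, 0, 1)


def test_time_reversal_swaps_kinds():
    rng = np.random.default_rng(41)
    g = _golgi_track(n=50)
    for _ in range(20):
        states = "".join(rng.choice(["F", "B"], size=50))
        fwd = state_series(
            _eres_from_states(states), [g], EventParams(min_dwell_frames=1), 0.1
        )
        rev = state_series(
            _eres_from_states(states[::-1]), [g], EventParams(min_dwell_frames=1), 0.1
        )
        n_cap_f = sum(e.kind == "capture" for e in fwd.events)
        n_rel_f = sum(e.kind == "release" for e in fwd.events)
        n_cap_r = sum(e.kind == "capture" for e in rev.events)
        n_rel_r = sum(e.kind == "release" for e in rev.events)
        assert (n_cap_f, n_rel_f) == (n_rel_r, n_cap_r)


# ---------------------------------------------------------------------------
# event_frequency


def test_single_golgi_two_captures():
    g = _golgi_track(n=201, track_id=1000)  # 20 s at 0.1 s/frame
    events = [
        Event(frame=50, time_s=5.0, kind="capture", golgi_track_id=1000, eres_track_id=0),
        Event(frame=150, time_s=15.0, kind="capture", golgi_track_id=1000, eres_track_id=1),
    ]
    freq = event_frequency(events, [g], 0.1, 10.0)
    assert len(freq) == 1
    assert freq["captures_per_window"].iloc[0] == pytest.approx(1.0)


def test_zero_events_zero_frequency():
    g = _golgi_track(n=201, track_id=1000)
    freq = event_frequency([], [g], 0.1, 10.0)
    assert freq["captures_per_window"].iloc[0] == 0.0
    assert freq["releases_per_window"].iloc[0] == 0.0


def test_short_observation_excluded():
    g = _golgi_track(n=50, track_id=1000)  # < 10 s
    freq = event_frequency([], [g], 0.1, 10.0)
    assert len(freq) == 0
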