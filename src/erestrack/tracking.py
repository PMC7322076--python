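"""Frame-to-frame particle linking, motion classification, per-frame
binding-state series and capture/release event statistics.

Linking is an optimal assignment per frame pair (minimum summed
displacement among candidates inside the gate), with gap closing up to
``max_gap`` frames at twice the single-frame gate. State series apply a
dwell-time hysteresis so transient proximity is not scored as capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import EventParams, MotionParams, TrackingParams
from .stats import mean_sem

__all__ = [
    "Track",
    "Event",
    "StateSeries",
    "MotionClass",
    "link_tracks",
    "classify_motion",
    "state_series",
    "events_from_tracks",
    "event_frequency",
]

_BIG = 1.0e12


@dataclass
class Track:
    """Time-linked particle; positions in nm, frames strictly increasing."""

    track_id: int
    kind: str  # 'eres' | 'golgi'
    frames: list[int] = field(default_factory=list)
    xy_nm: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frames_arr(self) -> np.ndarray:
        return np.asarray(self.frames, dtype=int)

    @property
    def xy_arr(self) -> np.ndarray:
        return np.asarray(self.xy_nm, dtype=float).reshape(-1, 2)

    def position_at(self, frame: int) -> np.ndarray | None:
        """Linearly interpolated position, None outside the track span."""
        f = self.frames_arr
        if frame < f[0] or frame > f[-1]:
            return None
        xy = self.xy_arr
        x = np.interp(frame, f, xy[:, 0])
        y = np.interp(frame, f, xy[:, 1])
        return np.array([x, y])


@dataclass
class Event:
    frame: int
    time_s: float
    kind: str  # 'capture' | 'release'
    golgi_track_id: int
    eres_track_id: int


@dataclass
class MotionClass:
    label: str  # 'directional' | 'random' | 'undefined'
    straightness: float
    mean_speed_nm_s: float


@dataclass
class StateSeries:
    """Hysteresis-filtered per-frame association state for one ERES track."""

    eres_track_id: int
    frames: np.ndarray
    state: np.ndarray  # golgi track id, -1 = FREE
    events: list[Event]


def link_tracks(
    detections: dict[int, np.ndarray] | list[tuple[int, np.ndarray]],
    params: TrackingParams | None = None,
    kind: str = "eres",
) -> list[Track]:
    """Link per-frame detections (frame -> (n, 2) nm positions) into tracks."""
    if params is None:
        params = TrackingParams()
    if isinstance(detections, dict):
        items = sorted(detections.items())
    else:
        items = sorted(detections, key=lambda kv: kv[0])

    tracks: list[Track] = []
    active: list[Track] = []
    for frame, xy in items:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        # retire tracks whose gap can no longer be closed
        still = []
        for tr in active:
            if frame - tr.frames[-1] <= params.max_gap + 1:
                still.append(tr)
        active = still

        assigned = np.full(len(xy), False)
        if active and len(xy):
            last_xy = np.array([tr.xy_nm[-1] for tr in active])
            gaps = np.array([frame - tr.frames[-1] for tr in active])
            gates = np.where(gaps == 1, params.max_disp_nm, 2.0 * params.max_disp_nm)
            dist = cdist(last_xy, xy)
            cost = np.where(dist <= gates[:, None], dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if dist[i, j] <= gates[i]:
                    active[i].frames.append(int(frame))
                    active[i].xy_nm.append(xy[j])
                    assigned[j] = True
        for j in np.where(~assigned)[0]:
            tr = Track(track_id=len(tracks), kind=kind)
            tr.frames.append(int(frame))
            tr.xy_nm.append(xy[j])
            tracks.append(tr)
            active.append(tr)
    return tracks


def classify_motion(
    track: Track,
    frame_interval_s: float,
    params: MotionParams | None = None,
) -> MotionClass:
    """Directional vs random from straightness and mean speed.

    straightness = net displacement / summed step lengths; directional
    requires straightness and mean speed above their thresholds.
    """
    if params is None:
        params = MotionParams()
    if len(track) < params.min_track_frames:
        return MotionClass("undefined", float("nan"), float("nan"))
    xy = track.xy_arr
    steps = np.diff(xy, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    path = float(step_len.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    duration = (track.frames[-1] - track.frames[0]) * frame_interval_s
    straightness = net / path if path > 0 else 0.0
    speed = path / duration if duration > 0 else 0.0
    label = (
        "directional"
        if straightness >= params.straightness_threshold
        and speed >= params.min_speed_nm_s
        else "random"
    )
    return MotionClass(label, straightness, speed)


def _interpolated_golgi_positions(
    golgi_tracks: list[Track], n_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """(n_golgi, T, 2) positions linearly interpolated across each Golgi
    track's own span, NaN outside it, plus the track-id vector."""
    ids = np.array([g.track_id for g in golgi_tracks], dtype=int)
    pos = np.full((len(golgi_tracks), n_frames, 2), np.nan)
    t_all = np.arange(n_frames)
    for k, g in enumerate(golgi_tracks):
        f = g.frames_arr
        xy = g.xy_arr
        inside = (t_all >= f[0]) & (t_all <= f[-1])
        pos[k, inside, 0] = np.interp(t_all[inside], f, xy[:, 0])
        pos[k, inside, 1] = np.interp(t_all[inside], f, xy[:, 1])
    return pos, ids


def _raw_states(
    eres_track: Track,
    golgi_tracks: list[Track],
    assoc_radius_nm: float,
    golgi_pos: np.ndarray | None = None,
    golgi_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    frames = eres_track.frames_arr
    states = np.full(len(frames), -1, dtype=int)
    if not golgi_tracks:
        return frames, states
    if golgi_pos is None:
        golgi_pos, golgi_ids = _interpolated_golgi_positions(
            golgi_tracks, int(frames[-1]) + 1
        )
    # golgi ids ascending so nearest-ties resolve to the lower id
    order = np.argsort(golgi_ids, kind="stable")
    golgi_pos, golgi_ids = golgi_pos[order], golgi_ids[order]
    xy = eres_track.xy_arr  # positions at the track's own frames
    gp = golgi_pos[:, frames, :]  # (n_golgi, n_track_frames, 2)
    with np.errstate(invalid="ignore"):
        d = np.linalg.norm(gp - xy[None, :, :], axis=-1)  # (n_golgi, n_frames)
    d = np.where(np.isnan(d), np.inf, d)
    best = np.argmin(np.round(d), axis=0)  # 1-nm tie tolerance, lower id wins
    best_d = d[best, np.arange(len(frames))]
    within = best_d <= assoc_radius_nm
    states[within] = golgi_ids[best[within]]
    return frames, states


def _dwell_filter(states: np.ndarray, min_dwell: int) -> np.ndarray:
    """Accept a state change only if the new state persists min_dwell
    consecutive samples; otherwise samples keep the prior state."""
    n = len(states)
    out = np.empty(n, dtype=int)
    if n == 0:
        return out
    # run-length encode
    runs: list[tuple[int, int, int]] = []  # (state, start, length)
    start = 0
    for i in range(1, n + 1):
        if i == n or states[i] != states[start]:
            runs.append((int(states[start]), start, i - start))
            start = i
    current = runs[0][0]
    for state, s, length in runs:
        if state != current and length >= min_dwell:
            current = state
        out[s : s + length] = current
    return out


def state_series(
    eres_track: Track,
    golgi_tracks: list[Track],
    params: EventParams | None = None,
    frame_interval_s: float = 0.1,
    _golgi_pos: np.ndarray | None = None,
    _golgi_ids: np.ndarray | None = None,
) -> StateSeries:
    """Dwell-filtered FREE/BOUND state series and its events."""
    if params is None:
        params = EventParams()
    frames, raw = _raw_states(
        eres_track, golgi_tracks, params.assoc_radius_nm, _golgi_pos, _golgi_ids
    )
    filt = _dwell_filter(raw, params.min_dwell_frames)

    events: list[Event] = []
    for k in range(1, len(filt)):
        prev, cur = filt[k - 1], filt[k]
        if prev == cur:
            continue
        frame = int(frames[k])
        t = frame * frame_interval_s
        if prev >= 0:
            events.append(Event(frame, t, "release", int(prev), eres_track.track_id))
        if cur >= 0:
            events.append(Event(frame, t, "capture", int(cur), eres_track.track_id))
    return StateSeries(
        eres_track_id=eres_track.track_id, frames=frames, state=filt, events=events
    )


def events_from_tracks(
    eres_tracks: list[Track],
    golgi_tracks: list[Track],
    params: EventParams | None = None,
    frame_interval_s: float = 0.1,
) -> list[Event]:
    events: list[Event] = []
    golgi_pos = golgi_ids = None
    if golgi_tracks and eres_tracks:
        n_frames = max(tr.frames[-1] for tr in eres_tracks) + 1
        golgi_pos, golgi_ids = _interpolated_golgi_positions(golgi_tracks, n_frames)
    for tr in eres_tracks:
        events.extend(
            state_series(
                tr, golgi_tracks, params, frame_interval_s,
                _golgi_pos=golgi_pos, _golgi_ids=golgi_ids,
            ).events
        )
    events.sort(key=lambda e: (e.frame, e.kind, e.golgi_track_id))
    return events


def event_frequency(
    events: list[Event],
    golgi_tracks: list[Track],
    frame_interval_s: float = 0.1,
    window_s: float = 10.0,
) -> pd.DataFrame:
    """Per-Golgi capture and release counts normalized to events per
    window (default 10 s). Golgi observed for less than one window are
    excluded."""
    rows = []
    for g in golgi_tracks:
        duration = (g.frames[-1] - g.frames[0]) * frame_interval_s
        if duration < window_s:
            continue
        n_cap = sum(
            1 for e in events if e.kind == "capture" and e.golgi_track_id == g.track_id
        )
        n_rel = sum(
            1 for e in events if e.kind == "release" and e.golgi_track_id == g.track_id
        )
        rows.append(
            {
                "golgi_track_id": g.track_id,
                "observed_s": duration,
                "n_captures": n_cap,
                "n_releases": n_rel,
                "captures_per_window": n_cap / duration * window_s,
                "releases_per_window": n_rel / duration * window_s,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "golgi_track_id",
            "observed_s",
            "n_captures",
            "n_releases",
            "captures_per_window",
            "releases_per_window",
        ],
    )


def frequency_summary(freq: pd.DataFrame) -> dict:
    """Ensemble mean +/- SEM of per-Golgi frequencies, plus pooled mean
    inter-event intervals."""
    out: dict = {}
    for kind, col, n_col in (
        ("capture", "captures_per_window", "n_captures"),
        ("release", "releases_per_window", "n_releases"),
    ):
        if len(freq) >= 2:
            m, s = mean_sem(freq[col])
        elif len(freq) == 1:
            m, s = float(freq[col].iloc[0]), float("nan")
        else:
            m, s = float("nan"), float("nan")
        total_events = int(freq[n_col].sum()) if len(freq) else 0
        total_time = float(freq["observed_s"].sum()) if len(freq) else 0.0
        out[f"{kind}_per_window_mean"] = m
        out[f"{kind}_per_window_sem"] = s
        out[f"{kind}_n_events"] = total_events
        out[f"{kind}_mean_interval_s"] = (
            total_time / total_events if total_events else float("nan")
        )
    return out
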