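"""End-to-end orchestration: simulate -> detect -> segment -> associate ->
track -> events -> summary, plus validation of a result bundle against
the generator's ground truth."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import __version__
from .association import classify_association
from .config import RunConfig, run_config_to_dict
from .detection import (
    detect_golgi,
    detect_puncta,
    golgi_to_dataframe,
    puncta_to_dataframe,
)
from .frames import FrameSeries
from .morphology import assign_subdomain, classify_subdomains, segment_er
from .simulate import GroundTruth, Renderer, simulate_scene
from .tracking import (
    Event,
    Track,
    classify_motion,
    event_frequency,
    events_from_tracks,
    frequency_summary,
    link_tracks,
)

logger = logging.getLogger("erestrack")

__all__ = ["PipelineResult", "run_pipeline", "validate_against_truth"]


@dataclass
class PipelineResult:
    """All tabular outputs of one pipeline run."""

    puncta: pd.DataFrame
    golgi: pd.DataFrame
    association: pd.DataFrame
    rings: pd.DataFrame
    subdomain_counts: pd.DataFrame
    tracks_table: pd.DataFrame
    events_table: pd.DataFrame
    frequencies: pd.DataFrame
    summary: pd.DataFrame
    eres_tracks: list[Track] = field(default_factory=list)
    golgi_tracks: list[Track] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    truth: GroundTruth | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.puncta.to_csv(out / "puncta.csv", index=False)
        self.golgi.to_csv(out / "golgi.csv", index=False)
        self.association.to_csv(out / "association.csv", index=False)
        self.rings.to_csv(out / "rings.csv", index=False)
        self.subdomain_counts.to_csv(out / "subdomain_counts.csv", index=False)
        self.tracks_table.to_csv(out / "tracks.csv", index=False)
        self.events_table.to_csv(out / "events.csv", index=False)
        self.frequencies.to_csv(out / "frequencies.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _config_hash(config: RunConfig) -> str:
    text = yaml.safe_dump(run_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _tracks_table(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, xy in zip(tr.frames, tr.xy_nm):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "kind": tr.kind,
                    "frame": f,
                    "x_nm": xy[0],
                    "y_nm": xy[1],
                }
            )
    return pd.DataFrame(rows, columns=["track_id", "kind", "frame", "x_nm", "y_nm"])


def run_pipeline(
    config: RunConfig,
    frames: FrameSeries | None = None,
    renderer: Renderer | None = None,
    write_outputs: bool = False,
) -> PipelineResult:
    """Execute the full analysis on a FrameSeries, a lazy Renderer, or a
    freshly simulated scene described by ``config.scene``.

    Identical config + seed produce identical outputs.
    """
    truth: GroundTruth | None = None
    if frames is None and renderer is None:
        if config.scene is None:
            raise ValueError("no input: provide frames, a renderer, or a scene")
        seed = config.seed if config.seed is not None else config.scene.seed
        truth, renderer = simulate_scene(config.scene, seed=seed)
    elif renderer is not None:
        truth = renderer.truth

    if renderer is not None:
        channel_names = renderer.channel_names
        n_frames = renderer.truth.n_frames
        pixel_size_nm = renderer.config.pixel_size_nm
        frame_interval_s = renderer.config.frame_interval_s

        # render lazily, holding only the current frame in memory
        _cache: dict[int, dict[str, np.ndarray]] = {}

        def get_frame(name: str, t: int) -> np.ndarray:
            if t not in _cache:
                _cache.clear()
                _cache[t] = renderer.frame(t)
            return _cache[t][name]

    else:
        channel_names = frames.channel_names
        n_frames = frames.n_frames
        pixel_size_nm = frames.pixel_size_nm
        frame_interval_s = frames.frame_interval_s

        def get_frame(name: str, t: int) -> np.ndarray:
            return frames.frame(name, t)

    det_p = config.detection
    assoc_p = config.association
    has_golgi = "golgi" in channel_names
    has_er = "er" in channel_names
    has_copii = "copii" in channel_names

    all_puncta_df = []
    all_golgi_df = []
    assoc_rows = []
    ring_rows = []
    coloc_counts = []  # (k_matched, n_b)
    bound_counts = []  # (n_bound, n_total)
    sub_rows = []
    eres_by_frame: dict[int, np.ndarray] = {}
    golgi_by_frame: dict[int, np.ndarray] = {}

    subdomain_map = None
    if has_er:
        er0 = get_frame("er", 0)
        er_mask, er_flags = segment_er(er0, pixel_size_nm, config.segmentation)
        if er_flags.get("saturated"):
            logger.warning("ER frame flagged as saturated; segmentation may be unreliable")
        subdomain_map = classify_subdomains(er_mask, pixel_size_nm, config.subdomains)

    for t in range(n_frames):
        puncta = detect_puncta(
            get_frame("eres", t), pixel_size_nm, det_p, frame_index=t, channel="eres"
        )
        all_puncta_df.append(puncta_to_dataframe(puncta))
        eres_by_frame[t] = np.array([[p.x_nm, p.y_nm] for p in puncta]).reshape(-1, 2)

        golgi = []
        if has_golgi:
            golgi = detect_golgi(
                get_frame("golgi", t), pixel_size_nm, assoc_p, frame_index=t
            )
            all_golgi_df.append(golgi_to_dataframe(golgi))
            golgi_by_frame[t] = np.array(
                [[g.x_nm, g.y_nm] for g in golgi]
            ).reshape(-1, 2)

            res = classify_association(
                puncta,
                golgi,
                assoc_radius_nm=assoc_p.assoc_radius_nm,
                min_ring_members=assoc_p.min_ring_members,
            )
            bound_counts.append((res.n_bound, len(puncta)))
            for i, p in enumerate(puncta):
                assoc_rows.append(
                    {
                        "frame": t,
                        "punctum_id": i,
                        "state": "BOUND" if res.golgi_id[i] >= 0 else "FREE",
                        "golgi_id": res.golgi_id[i],
                        "distance_nm": res.distance_nm[i],
                    }
                )
            rings_t = res.rings.copy()
            rings_t.insert(0, "frame", t)
            ring_rows.append(rings_t)
            free_idx = np.where(res.golgi_id < 0)[0]
        else:
            free_idx = np.arange(len(puncta))

        if has_copii:
            from .association import colocalize

            puncta_b = detect_puncta(
                get_frame("copii", t), pixel_size_nm, det_p,
                frame_index=t, channel="copii",
            )
            all_puncta_df.append(puncta_to_dataframe(puncta_b))
            match = colocalize(puncta, puncta_b, assoc_p.match_radius_nm)
            coloc_counts.append((len(match.pairs), len(puncta_b)))

        if subdomain_map is not None and len(free_idx):
            xy_px = np.array(
                [[puncta[i].x_px, puncta[i].y_px] for i in free_idx]
            ).reshape(-1, 2)
            _, summary = assign_subdomain(xy_px, subdomain_map, config.subdomains)
            summary["frame"] = t
            sub_rows.append(summary)

        if config.verbosity >= 2:
            logger.info("frame %d: %d puncta, %d golgi", t, len(puncta), len(golgi))

    # tracking and events
    eres_tracks = link_tracks(eres_by_frame, config.tracking, kind="eres")
    golgi_tracks = (
        link_tracks(golgi_by_frame, config.tracking, kind="golgi") if has_golgi else []
    )
    for tr in golgi_tracks:
        tr.track_id += 100000  # keep golgi and eres track ids disjoint

    events = events_from_tracks(
        eres_tracks, golgi_tracks, config.events, frame_interval_s
    )
    freq = event_frequency(
        events, golgi_tracks, frame_interval_s, config.events.window_s
    )

    # summary
    summary_rows = []

    def add(name, value, **extra):
        summary_rows.append({"quantity": name, "value": value, **extra})

    if coloc_counts:
        from .stats import pool_replicates

        pooled, _ = pool_replicates(coloc_counts)
        add("coloc_fraction_of_b", pooled.point, low=pooled.low, high=pooled.high,
            n=pooled.n)
    if bound_counts:
        from .stats import pool_replicates

        pooled, _ = pool_replicates(bound_counts)
        n_bound = pooled.k
        n_total = pooled.n
        n_free = n_total - n_bound
        add("bound_fraction", pooled.point, low=pooled.low, high=pooled.high, n=n_total)
        add("free_to_bound_ratio",
            n_free / n_bound if n_bound else float("nan"), n=n_total)
    if sub_rows:
        tot_assigned = sum(r["n_assigned"] for r in sub_rows)
        tot_tr = sum(r["n_tubule"] + r["n_rim"] for r in sub_rows)
        if tot_assigned:
            add("free_on_tubule_or_rim_fraction", tot_tr / tot_assigned, n=tot_assigned)
    if ring_rows:
        rings_all = pd.concat(ring_rows, ignore_index=True)
        valid = rings_all["ring_diameter_nm"].dropna()
        if len(valid):
            add("mean_ring_diameter_nm", float(valid.mean()), n=int(len(valid)))
    fsum = frequency_summary(freq)
    for key, value in fsum.items():
        add(key, value)

    # motion classification summary
    motions = [classify_motion(tr, frame_interval_s, config.motion) for tr in eres_tracks]
    defined = [m for m in motions if m.label != "undefined"]
    if defined:
        frac_dir = sum(m.label == "directional" for m in defined) / len(defined)
        add("directional_track_fraction", frac_dir, n=len(defined))

    summary = pd.DataFrame(summary_rows, columns=["quantity", "value", "low", "high", "n"])

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed if config.seed is not None else (
            config.scene.seed if config.scene else None
        ),
        "erestrack_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "n_frames": n_frames,
        "status": "OK",
    }

    result = PipelineResult(
        puncta=pd.concat(all_puncta_df, ignore_index=True)
        if all_puncta_df
        else puncta_to_dataframe([]),
        golgi=pd.concat(all_golgi_df, ignore_index=True)
        if all_golgi_df
        else golgi_to_dataframe([]),
        association=pd.DataFrame(
            assoc_rows, columns=["frame", "punctum_id", "state", "golgi_id", "distance_nm"]
        ),
        rings=pd.concat(ring_rows, ignore_index=True)
        if ring_rows
        else pd.DataFrame(columns=["frame", "golgi_id", "n_members", "ring_diameter_nm"]),
        subdomain_counts=pd.DataFrame(sub_rows),
        tracks_table=_tracks_table(eres_tracks + golgi_tracks),
        events_table=pd.DataFrame(
            [
                {
                    "time_s": e.time_s,
                    "frame": e.frame,
                    "kind": e.kind,
                    "golgi_track_id": e.golgi_track_id,
                    "eres_track_id": e.eres_track_id,
                }
                for e in events
            ],
            columns=["time_s", "frame", "kind", "golgi_track_id", "eres_track_id"],
        ),
        frequencies=freq,
        summary=summary,
        eres_tracks=eres_tracks,
        golgi_tracks=golgi_tracks,
        events=events,
        truth=truth,
        manifest=manifest,
    )
    if write_outputs:
        result.write(config.out_dir)
    return result


# ---------------------------------------------------------------------------
# validation against ground truth


def _match_points(
    true_xy: np.ndarray, det_xy: np.ndarray, radius: float
) -> tuple[int, int, int, np.ndarray]:
    """Optimal matching; returns (tp, fn, fp, matched distances)."""
    n_t, n_d = len(true_xy), len(det_xy)
    if n_t == 0 or n_d == 0:
        return 0, n_t, n_d, np.empty(0)
    dist = cdist(true_xy, det_xy)
    cost = np.where(dist <= radius, dist, 1e12)
    rows, cols = linear_sum_assignment(cost)
    ok = dist[rows, cols] <= radius
    tp = int(ok.sum())
    return tp, n_t - tp, n_d - tp, dist[rows[ok], cols[ok]]


def validate_against_truth(
    result: PipelineResult,
    truth: GroundTruth | None = None,
    match_radius_nm: float = 200.0,
    event_tolerance_frames: int = 8,
) -> dict:
    """Compare a result bundle with the generating truth.

    Refuses bundles without an attached GroundTruth (real data has none).
    """
    truth = truth if truth is not None else result.truth
    if truth is None:
        raise ValueError("no ground truth available: refusing to validate real data")
    px = truth.pixel_size_nm

    # detection metrics over all frames
    tp = fn = fp = 0
    sq_errs: list[float] = []
    det = result.puncta[result.puncta["channel"] == "eres"]
    for t in range(truth.n_frames):
        true_xy = truth.puncta_xy[t] * px
        det_t = det[det["frame"] == t]
        det_xy = det_t[["x_nm", "y_nm"]].to_numpy().reshape(-1, 2)
        tp_t, fn_t, fp_t, dists = _match_points(true_xy, det_xy, match_radius_nm)
        tp, fn, fp = tp + tp_t, fn + fn_t, fp + fp_t
        sq_errs.extend(dists**2)

    metrics = {
        "detection_recall": tp / (tp + fn) if tp + fn else float("nan"),
        "detection_precision": tp / (tp + fp) if tp + fp else float("nan"),
        "localization_rmse_nm": float(np.sqrt(np.mean(sq_errs))) if sq_errs else float("nan"),
    }

    # track recovery: a truth particle is recovered if one detected track
    # follows it (nearest within radius) for >= 80% of its frames
    if result.eres_tracks:
        n_recovered = 0
        for i in range(truth.n_puncta):
            best_cover = 0.0
            true_traj = truth.puncta_xy[:, i, :] * px
            for tr in result.eres_tracks:
                f = tr.frames_arr
                f = f[f < truth.n_frames]
                if len(f) == 0:
                    continue
                d = np.linalg.norm(tr.xy_arr[: len(f)] - true_traj[f], axis=1)
                cover = np.sum(d <= match_radius_nm) / truth.n_frames
                best_cover = max(best_cover, cover)
            if best_cover >= 0.8:
                n_recovered += 1
        metrics["track_recovery"] = n_recovered / truth.n_puncta if truth.n_puncta else float("nan")

    # event metrics: same kind, matching golgi (by position), within tolerance
    true_events = truth.event_table()
    if len(true_events) or result.events:
        golgi_map = {}
        for g in result.golgi_tracks:
            p0 = g.xy_arr[0] / px
            d = np.linalg.norm(truth.golgi_xy[g.frames[0]] - p0, axis=1)
            golgi_map[g.track_id] = int(np.argmin(d)) if len(d) else -1
        det_events = [
            (e.kind, golgi_map.get(e.golgi_track_id, -1), e.frame) for e in result.events
        ]
        used = np.zeros(len(det_events), dtype=bool)
        tp_e = 0
        for _, row in true_events.iterrows():
            for j, (kind, gid, frame) in enumerate(det_events):
                if used[j]:
                    continue
                if (
                    kind == row["kind"]
                    and gid == row["golgi_id"]
                    and abs(frame - row["frame"]) <= event_tolerance_frames
                ):
                    used[j] = True
                    tp_e += 1
                    break
        n_true, n_det = len(true_events), len(det_events)
        metrics["event_recall"] = tp_e / n_true if n_true else float("nan")
        metrics["event_precision"] = tp_e / n_det if n_det else float("nan")
        f1_den = (
            metrics["event_recall"] + metrics["event_precision"]
            if n_true and n_det
            else 0
        )
        metrics["event_f1"] = (
            2 * metrics["event_recall"] * metrics["event_precision"] / f1_den
            if f1_den
            else float("nan")
        )
    return metrics
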