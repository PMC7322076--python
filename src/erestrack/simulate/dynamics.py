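"""Stochastic scene dynamics: streaming, diffusion, capture and release.

Per frame of duration dt:

* Golgi advect with the (shared) cytoplasmic-streaming velocity — zero
  when the cytoskeleton is inhibited — plus a Brownian step.
* Bound puncta ride their Golgi, holding a slowly wiggling position on
  the beaded ring.
* Free puncta take Brownian steps constrained to the ER mask (projected
  back to the nearest ER pixel when they stray).
* A bound punctum detaches with probability 1 - exp(-k_release dt); it
  then migrates radially outward until it reaches the ER. A free punctum
  within the capture radius of a Golgi commits to capture with
  probability 1 - exp(-k_capture dt) and migrates onto the ring.

Release events are logged at detachment, capture events on arrival at
the ring, so the event log alternates per (punctum, Golgi) pair.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..config import SceneConfig
from .truth import FREE, TRANSIT, GroundTruth

__all__ = ["simulate_dynamics"]

_BOUND, _FREE, _RELEASING, _CAPTURING = 0, 1, 2, 3


def simulate_dynamics(
    config: SceneConfig,
    initial: GroundTruth,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Expand a single-frame GroundTruth into ``config.n_frames`` frames."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    px = config.pixel_size_nm
    dt = config.frame_interval_s
    h, w = initial.network.mask.shape
    n_frames = config.n_frames
    n_golgi = initial.n_golgi
    n_puncta = initial.n_puncta

    # nearest-ER lookup for projecting free puncta back onto the network
    mask = initial.network.mask
    if mask.any():
        edt_off, (iy, ix) = ndimage.distance_transform_edt(
            ~mask, return_indices=True
        )
    else:
        edt_off = np.zeros((h, w))
        iy, ix = np.indices((h, w))

    def project_to_er(pos_xy: np.ndarray) -> np.ndarray:
        c = int(np.clip(round(pos_xy[0]), 0, w - 1))
        r = int(np.clip(round(pos_xy[1]), 0, h - 1))
        if edt_off[r, c] <= 1.0:
            return pos_xy
        return np.array([ix[r, c], iy[r, c]], dtype=float)

    # physical steps in pixels
    sd_free = np.sqrt(2.0 * config.diffusion_coeff_nm2_s * dt) / px
    sd_golgi = np.sqrt(2.0 * config.golgi_diffusion_coeff_nm2_s * dt) / px
    v_stream = config.streaming_speed * dt / px
    theta = rng.uniform(0, 2 * np.pi)
    stream_vec = v_stream * np.array([np.cos(theta), np.sin(theta)])
    escape_step = config.escape_speed_nm_s * dt / px
    ring_r = config.ring_radius_px
    capture_r = config.capture_radius / px
    p_cap = 1.0 - np.exp(-config.k_capture_per_s * dt)
    p_rel = 1.0 - np.exp(-config.k_release_per_s * dt)

    golgi = np.zeros((n_frames, n_golgi, 2))
    puncta = np.zeros((n_frames, n_puncta, 2))
    states = np.full((n_frames, n_puncta), FREE, dtype=np.int16)
    golgi[0] = initial.golgi_xy[0]
    puncta[0] = initial.puncta_xy[0]
    states[0] = initial.puncta_state[0]

    mode = np.where(initial.puncta_state[0] >= 0, _BOUND, _FREE)
    target = np.where(initial.puncta_state[0] >= 0, initial.puncta_state[0], -1)
    ring_angle = np.zeros(n_puncta)
    for i in range(n_puncta):
        if mode[i] == _BOUND:
            d = puncta[0, i] - golgi[0, target[i]]
            ring_angle[i] = np.arctan2(d[1], d[0])

    events: list[dict] = []
    margin = config.cavity_radius_px + 2.0

    for t in range(1, n_frames):
        # Golgi motion (reflected at a border margin)
        step = stream_vec + rng.normal(0.0, sd_golgi, size=(n_golgi, 2))
        g = golgi[t - 1] + step
        for axis, limit in ((0, w), (1, h)):
            lo, hi = margin, limit - 1 - margin
            if hi > lo:
                g[:, axis] = np.where(g[:, axis] < lo, 2 * lo - g[:, axis], g[:, axis])
                g[:, axis] = np.where(g[:, axis] > hi, 2 * hi - g[:, axis], g[:, axis])
        golgi[t] = g

        for i in range(n_puncta):
            m = mode[i]
            pos = puncta[t - 1, i].copy()
            if m == _BOUND:
                gid = target[i]
                if p_rel > 0 and rng.random() < p_rel:
                    mode[i] = _RELEASING
                    events.append(
                        {
                            "frame": t,
                            "time_s": t * dt,
                            "kind": "release",
                            "golgi_id": int(gid),
                            "punctum_id": int(i),
                        }
                    )
                    # outward first step
                    d = pos - golgi[t, gid]
                    nrm = np.linalg.norm(d)
                    direction = d / nrm if nrm > 0 else np.array([1.0, 0.0])
                    pos = pos + direction * escape_step
                    states[t, i] = TRANSIT
                else:
                    ring_angle[i] += rng.normal(0.0, 0.02)
                    r = ring_r + rng.normal(0.0, 25.0 / px)
                    pos = golgi[t, gid] + r * np.array(
                        [np.cos(ring_angle[i]), np.sin(ring_angle[i])]
                    )
                    states[t, i] = gid
            elif m == _RELEASING:
                gid = target[i]
                d = pos - golgi[t, gid]
                nrm = np.linalg.norm(d)
                direction = d / nrm if nrm > 0 else np.array([1.0, 0.0])
                pos = pos + direction * escape_step
                c = int(np.clip(round(pos[0]), 0, w - 1))
                r_ = int(np.clip(round(pos[1]), 0, h - 1))
                if edt_off[r_, c] <= 1.0:
                    mode[i] = _FREE
                    target[i] = -1
                    states[t, i] = FREE
                else:
                    states[t, i] = TRANSIT
            elif m == _CAPTURING:
                gid = target[i]
                goal = golgi[t, gid] + ring_r * np.array(
                    [np.cos(ring_angle[i]), np.sin(ring_angle[i])]
                )
                d = goal - pos
                nrm = np.linalg.norm(d)
                if nrm <= escape_step:
                    pos = goal
                    mode[i] = _BOUND
                    states[t, i] = gid
                    events.append(
                        {
                            "frame": t,
                            "time_s": t * dt,
                            "kind": "capture",
                            "golgi_id": int(gid),
                            "punctum_id": int(i),
                        }
                    )
                else:
                    pos = pos + d / nrm * escape_step
                    states[t, i] = TRANSIT
            else:  # _FREE
                pos = pos + rng.normal(0.0, sd_free, size=2)
                pos[0] = np.clip(pos[0], 0.0, w - 1.0)
                pos[1] = np.clip(pos[1], 0.0, h - 1.0)
                pos = project_to_er(pos)
                states[t, i] = FREE
                if p_cap > 0 and n_golgi:
                    dists = np.linalg.norm(golgi[t] - pos, axis=1)
                    gid = int(np.argmin(dists))
                    if dists[gid] <= capture_r and rng.random() < p_cap:
                        mode[i] = _CAPTURING
                        target[i] = gid
                        d = pos - golgi[t, gid]
                        ring_angle[i] = np.arctan2(d[1], d[0])
                        states[t, i] = TRANSIT
            puncta[t, i] = pos

    return GroundTruth(
        pixel_size_nm=px,
        frame_interval_s=dt,
        network=initial.network,
        golgi_xy=golgi,
        puncta_xy=puncta,
        puncta_state=states,
        puncta_fwhm_nm=initial.puncta_fwhm_nm,
        puncta_subdomain0=initial.puncta_subdomain0,
        events=events,
        coloc=initial.coloc,
    )
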