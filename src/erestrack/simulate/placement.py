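"""Initial placement of Golgi blobs and ERES-like puncta on the ER truth.

Golgi centroids go into distinct cavities; the bound fraction of puncta is
arranged on beaded rings around them; free puncta land on ER pixels drawn
from the configured subdomain probabilities. Placement enforces a minimum
separation between puncta so that every generated object is a resolvable
diffraction-limited spot.
"""

from __future__ import annotations

import numpy as np

from ..config import SceneConfig
from ..morphology import SHEET, SHEET_RIM, TUBULE
from .truth import FREE, ColocTruth, GroundTruth, NetworkTruth

__all__ = ["place_objects"]

_SUBDOMAIN_ORDER = (TUBULE, SHEET_RIM, SHEET)  # matches free_subdomain_probs


def _ring_angles(k: int, rng: np.random.Generator) -> np.ndarray:
    """Evenly spread angles with random rotation and jitter: beads on a
    ring stay individually resolvable."""
    if k == 0:
        return np.empty(0)
    base = np.linspace(0.0, 2 * np.pi, k, endpoint=False)
    jitter = rng.uniform(-0.25, 0.25, size=k) * (2 * np.pi / k)
    return base + rng.uniform(0, 2 * np.pi) + jitter


def place_objects(
    config: SceneConfig,
    network: NetworkTruth,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Place Golgi and puncta; returns a single-frame GroundTruth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    px = config.pixel_size_nm
    h, w = network.mask.shape

    n_bound = int(round(config.frac_bound * config.n_puncta))
    n_free = config.n_puncta - n_bound
    if n_bound > 0 and config.n_golgi == 0:
        raise ValueError("frac_bound > 0 requires n_golgi > 0")

    # Golgi at cavity centres (already (x, y)) with a jitter small enough
    # to keep the ring inside the cavity
    golgi_xy = network.golgi_cavity_centers.astype(float).copy().reshape(-1, 2)
    slack_px = max(config.cavity_radius_px - config.ring_radius_px - 2.0, 0.0)
    if len(golgi_xy):
        golgi_xy += rng.uniform(-0.5, 0.5, size=golgi_xy.shape) * min(slack_px, 1.5)

    placed_xy: list[np.ndarray] = []  # (x, y)
    state: list[int] = []
    subdomain0: list[int] = []
    min_sep_px = config.min_puncta_separation_nm / px

    # bound puncta: round-robin over Golgi, beads on the ring
    if n_bound:
        counts = np.bincount(
            np.arange(n_bound) % config.n_golgi, minlength=config.n_golgi
        )
        ring_r_px = config.ring_radius_px
        for g in range(config.n_golgi):
            k = counts[g]
            angles = _ring_angles(k, rng)
            radii = ring_r_px + rng.normal(0.0, 40.0 / px, size=k)
            for a, r in zip(angles, radii):
                pos = golgi_xy[g] + r * np.array([np.cos(a), np.sin(a)])
                placed_xy.append(pos)
                state.append(g)
                subdomain0.append(0)

    # free puncta on ER pixels of the drawn subdomain
    labels = network.labels
    pools = {code: np.argwhere(labels == code) for code in _SUBDOMAIN_ORDER}
    draws = rng.multinomial(n_free, config.free_subdomain_probs)
    for code, count in zip(_SUBDOMAIN_ORDER, draws):
        pool = pools[code]
        if count > 0 and len(pool) == 0:
            raise ValueError(
                f"subdomain {code} has zero pixels but positive placement probability"
            )
        placed_for_code = 0
        attempts = 0
        while placed_for_code < count:
            attempts += 1
            if attempts > 400 * max(count, 1):
                raise RuntimeError(
                    "could not satisfy min_puncta_separation_nm; reduce n_puncta"
                )
            yx = pool[rng.integers(len(pool))]
            pos = np.array([yx[1], yx[0]], dtype=float) + rng.uniform(-0.45, 0.45, 2)
            if placed_xy and np.min(
                np.linalg.norm(np.array(placed_xy) - pos, axis=1)
            ) < min_sep_px:
                continue
            if len(golgi_xy) and np.min(
                np.linalg.norm(golgi_xy - pos, axis=1)
            ) < config.cavity_radius_px:
                continue
            placed_xy.append(pos)
            state.append(FREE)
            subdomain0.append(int(code))
            placed_for_code += 1

    puncta_xy = (
        np.array(placed_xy, dtype=float) if placed_xy else np.empty((0, 2))
    )
    golgi_xy_out = golgi_xy

    fwhm = rng.uniform(*config.punctum_fwhm_nm, size=len(puncta_xy))

    truth = GroundTruth(
        pixel_size_nm=px,
        frame_interval_s=config.frame_interval_s,
        network=network,
        golgi_xy=golgi_xy_out[None, :, :],
        puncta_xy=puncta_xy[None, :, :],
        puncta_state=np.array(state, dtype=np.int16)[None, :],
        puncta_fwhm_nm=fwhm,
        puncta_subdomain0=np.array(subdomain0, dtype=np.uint8),
    )

    if config.coloc_fraction is not None:
        truth.coloc = _place_coloc_channel(config, truth, rng)
    return truth


def _place_coloc_channel(
    config: SceneConfig, truth: GroundTruth, rng: np.random.Generator
) -> ColocTruth:
    """Second puncta channel: a configured fraction of its spots sit on
    channel-A puncta, the rest land on ER well away from any A punctum."""
    px = config.pixel_size_nm
    a_xy = truth.puncta_xy[0]
    n_b = len(a_xy)
    n_on = int(round(config.coloc_fraction * n_b))
    chosen = rng.permutation(n_b)[:n_on]

    xy = []
    on_a = []
    a_index = []
    for i in chosen:
        offset = rng.normal(0.0, 15.0 / px, size=2)
        xy.append(a_xy[i] + offset)
        on_a.append(True)
        a_index.append(int(i))

    # off-A spots: on ER, >= 700 nm from every A punctum and placed B
    er_yx = np.argwhere(truth.network.mask)
    min_clear_px = 700.0 / px
    attempts = 0
    while len(xy) < n_b:
        attempts += 1
        if attempts > 40000:
            raise RuntimeError("could not place non-colocalized channel-B puncta")
        p_yx = er_yx[rng.integers(len(er_yx))]
        pos = np.array([p_yx[1], p_yx[0]], dtype=float) + rng.uniform(-0.45, 0.45, 2)
        if len(a_xy) and np.min(np.linalg.norm(a_xy - pos, axis=1)) < min_clear_px:
            continue
        cur = np.array(xy)
        if len(cur) and np.min(np.linalg.norm(cur - pos, axis=1)) < min_clear_px:
            continue
        xy.append(pos)
        on_a.append(False)
        a_index.append(-1)

    return ColocTruth(
        xy_px=np.array(xy),
        fwhm_nm=rng.uniform(*config.punctum_fwhm_nm, size=n_b),
        on_a=np.array(on_a, dtype=bool),
        a_index=np.array(a_index, dtype=int),
    )
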