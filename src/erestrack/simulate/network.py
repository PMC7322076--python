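"""Synthetic cortical-ER network geometry.

Builds a connected polygonal tubule lattice with attached sheet patches
and, for each Golgi to be placed, an enclosed circular cavity ringed by ER
membrane. Truth subdomain labels are produced by running the package's own
width-based classifier on the clean binary mask, so placement and
downstream checks share one definition of tubule / sheet / sheet rim.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import dilation as binary_dilation, disk as disk_strel

from ..config import SceneConfig, SubdomainParams
from .truth import NetworkTruth

__all__ = ["generate_er_network"]


def _segment_point_distance(p0, p1, centers) -> np.ndarray:
    """Distance from each of `centers` to segment p0-p1."""
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    denom = float(d @ d)
    if denom == 0:
        return np.linalg.norm(centers - p0, axis=1)
    t = np.clip((centers - p0) @ d / denom, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(centers - proj, axis=1)


def _draw_thick_line(thin: np.ndarray, p0, p1) -> None:
    rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1])))
    h, w = thin.shape
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    thin[rr[ok], cc[ok]] = True


def _place_cavity_centers(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.field_size_px
    r = config.cavity_radius_px
    margin = r + 6.0
    min_sep = 2.0 * r + 14.0
    centers: list[np.ndarray] = []
    for _ in range(4000):
        if len(centers) == config.n_golgi:
            break
        cand = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < config.n_golgi:
        raise RuntimeError(
            f"could not place {config.n_golgi} non-overlapping cavities in a "
            f"{h}x{w} field"
        )
    return np.array(centers).reshape(-1, 2)  # (y, x)


def generate_er_network(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> NetworkTruth:
    """Generate the ER mask, truth subdomain labels and cavity record."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    cavity_r = config.cavity_radius_px
    centers_yx = _place_cavity_centers(config, rng)

    # jittered lattice nodes, kept clear of cavity interiors
    s = config.lattice_spacing_px
    ys = np.arange(s // 2, h - 2, s)
    xs = np.arange(s // 2, w - 2, s)
    nodes = np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1).reshape(-1, 2).astype(float)
    nodes += rng.uniform(-0.3 * s, 0.3 * s, size=nodes.shape)
    nodes[:, 0] = np.clip(nodes[:, 0], 1, h - 2)
    nodes[:, 1] = np.clip(nodes[:, 1], 1, w - 2)
    if len(centers_yx):
        d = np.linalg.norm(nodes[:, None, :] - centers_yx[None, :, :], axis=-1)
        nodes = nodes[d.min(axis=1) > cavity_r + 4.0]

    thin = np.zeros((h, w), dtype=bool)
    if len(nodes) >= 3:
        tri = Delaunay(nodes)
        edges = set()
        for simplex in tri.simplices:
            for a, b in ((0, 1), (1, 2), (0, 2)):
                e = tuple(sorted((simplex[a], simplex[b])))
                edges.add(e)
        for i, j in sorted(edges):
            p0, p1 = nodes[i], nodes[j]
            if np.linalg.norm(p0 - p1) > 2.3 * s:
                continue
            if len(centers_yx) and _segment_point_distance(p0, p1, centers_yx).min() < cavity_r + 2.0:
                continue
            _draw_thick_line(thin, p0, p1)

    # cavity rings plus spokes tying each ring into the lattice
    from skimage.draw import circle_perimeter

    for cy, cx in centers_yx:
        rr, cc = circle_perimeter(int(round(cy)), int(round(cx)), int(round(cavity_r)), shape=(h, w))
        thin[rr, cc] = True
        if len(nodes):
            dist = np.linalg.norm(nodes - np.array([cy, cx]), axis=1)
            for k in np.argsort(dist)[:3]:
                node = nodes[k]
                vec = node - np.array([cy, cx])
                start = np.array([cy, cx]) + vec / np.linalg.norm(vec) * cavity_r
                _draw_thick_line(thin, start, node)

    dil_r = max((config.tubule_width_px - 1) // 2, 1)
    mask = binary_dilation(thin, disk_strel(dil_r))

    # sheet patches attached to the lattice
    r_lo, r_hi = config.sheet_radius_px_range
    if len(nodes) and config.n_sheets > 0:
        order = rng.permutation(len(nodes))
        n_drawn = 0
        for k in order:
            if n_drawn >= config.n_sheets:
                break
            node = nodes[k]
            radius = int(rng.integers(r_lo, r_hi + 1))
            if len(centers_yx):
                d = np.linalg.norm(centers_yx - node, axis=1)
                if d.min() < cavity_r + radius + 3.0:
                    continue
            if (
                node[0] < radius + 1
                or node[0] > h - radius - 2
                or node[1] < radius + 1
                or node[1] > w - radius - 2
            ):
                continue
            rr, cc = draw_disk((node[0], node[1]), radius, shape=(h, w))
            mask[rr, cc] = True
            n_drawn += 1

    def _clear_cavities(m: np.ndarray) -> None:
        for cy, cx in centers_yx:
            rr, cc = draw_disk((cy, cx), cavity_r - 0.5, shape=(h, w))
            m[rr, cc] = False

    _clear_cavities(mask)

    # stitch the network into one 8-connected component
    for _ in range(50):
        lab = cc_label(mask, connectivity=2)
        n_comp = lab.max()
        if n_comp <= 1:
            break
        sizes = np.bincount(lab.ravel())[1:]
        main = int(np.argmax(sizes)) + 1
        # nearest pixel pair between the main component and the rest
        from scipy.spatial import cKDTree

        main_yx = np.argwhere(lab == main)
        rest_yx = np.argwhere((lab > 0) & (lab != main))
        tree = cKDTree(main_yx)
        dist, idx = tree.query(rest_yx, workers=-1)
        j = int(np.argmin(dist))
        p_rest, p_main = rest_yx[j], main_yx[idx[j]]
        bridge = np.zeros_like(thin)
        _draw_thick_line(bridge, p_rest, p_main)
        mask |= binary_dilation(bridge, disk_strel(dil_r))
        _clear_cavities(mask)
    else:
        raise RuntimeError("failed to connect ER network")

    # truth labels via the package's own width-based classifier
    from ..morphology import classify_subdomains

    sub = classify_subdomains(mask, config.pixel_size_nm, SubdomainParams())
    centers_xy = centers_yx[:, ::-1].copy()
    return NetworkTruth(
        mask=mask,
        labels=sub.labels,
        cavities=sub.cavities,
        golgi_cavity_centers=centers_xy,
    )
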