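"""Colocalization matching, Golgi association, ring diameters."""

import itertools

import numpy as np
import pytest

from erestrack.association import (
    classify_association,
    colocalize,
    ring_diameter,
)
from erestrack.detection import GolgiObject, Punctum


def _puncta(xy_nm, channel="eres"):
    return [
        Punctum(
            frame_index=0, channel=channel, x_px=x / 65, y_px=y / 65,
            x_nm=x, y_nm=y, fwhm_nm=400.0, peak_intensity=1.0,
        )
        for x, y in xy_nm
    ]


def _golgi(xy_nm):
    out = [
        GolgiObject(
            frame_index=0, x_px=x / 65, y_px=y / 65, x_nm=x, y_nm=y,
            equivalent_diameter_nm=1000.0, area_px=100, id=i,
        )
        for i, (x, y) in enumerate(xy_nm)
    ]
    return out


def _brute_force_best_matching(xy_a, xy_b, radius):
    """Enumerate all one-to-one matchings; maximize pairs then minimize
    total distance. Independent oracle for small n."""
    n_a, n_b = len(xy_a), len(xy_b)
    best = (0, 0.0, frozenset())
    idx_b = list(range(n_b))
    for k in range(min(n_a, n_b), -1, -1):
        found = False
        for subset_a in itertools.combinations(range(n_a), k):
            for perm_b in itertools.permutations(idx_b, k):
                dists = [
                    np.linalg.norm(np.array(xy_a[i]) - np.array(xy_b[j]))
                    for i, j in zip(subset_a, perm_b)
                ]
                if all(d <= radius for d in dists):
                    found = True
                    total = sum(dists)
                    cand = (k, -total, frozenset(zip(subset_a, perm_b)))
                    if cand[:2] > best[:2]:
                        best = cand
        if found:
            break
    return best[0], -best[1], best[2]


# ---------------------------------------------------------------------------
# colocalize


def test_identical_sets_fraction_one():
    xy = [(0.0, 0.0), (500.0, 0.0), (0.0, 900.0)]
    m = colocalize(_puncta(xy), _puncta(xy, "copii"), 300.0)
    assert m.matched_fraction_of_b == 1.0
    assert all(d == 0.0 for _, _, d in m.pairs)


def test_disjoint_sets_fraction_zero():
    a = [(0.0, 0.0)]
    b = [(5000.0, 0.0), (0.0, 5000.0)]
    m = colocalize(_puncta(a), _puncta(b, "copii"), 200.0)
    assert m.matched_fraction_of_b == 0.0
    assert m.unmatched_b == [0, 1]


def test_empty_inputs_nan_fraction():
    m = colocalize([], [], 300.0)
    assert np.isnan(m.matched_fraction_of_b)
    assert m.pairs == []


def test_spec_example_one_pair():
    a = [(0.0, 0.0), (1000.0, 0.0)]
    b = [(50.0, 0.0), (5000.0, 0.0)]
    m = colocalize(_puncta(a), _puncta(b, "copii"), 200.0)
    assert len(m.pairs) == 1
    assert m.pairs[0][:2] == (0, 0)
    assert m.pairs[0][2] == pytest.approx(50.0)
    assert m.matched_fraction_of_b == 0.5


@pytest.mark.parametrize("seed", range(8))
def test_matching_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(1, 7, size=2)
    xy_a = rng.uniform(0, 1500, size=(n_a, 2))
    xy_b = rng.uniform(0, 1500, size=(n_b, 2))
    radius = 500.0
    m = colocalize(_puncta(xy_a), _puncta(xy_b, "copii"), radius)
    k, total, _pairs = _brute_force_best_matching(xy_a, xy_b, radius)
    assert len(m.pairs) == k
    assert m.total_distance_nm == pytest.approx(total, abs=1e-6)


def test_pair_distances_symmetric_under_swap():
    rng = np.random.default_rng(3)
    xy_a = rng.uniform(0, 2000, size=(5, 2))
    xy_b = rng.uniform(0, 2000, size=(6, 2))
    m_ab = colocalize(_puncta(xy_a), _puncta(xy_b, "copii"), 600.0)
    m_ba = colocalize(_puncta(xy_b, "copii"), _puncta(xy_a), 600.0)
    pairs_ab = {(i, j) for i, j, _ in m_ab.pairs}
    pairs_ba = {(j, i) for i, j, _ in m_ba.pairs}
    assert pairs_ab == pairs_ba


def test_matched_fraction_monotone_in_radius():
    rng = np.random.default_rng(5)
    xy_a = rng.uniform(0, 3000, size=(10, 2))
    xy_b = rng.uniform(0, 3000, size=(10, 2))
    fractions = [
        colocalize(_puncta(xy_a), _puncta(xy_b, "copii"), r).matched_fraction_of_b
        for r in (100, 300, 600, 1200, 2400)
    ]
    assert all(b >= a for a, b in zip(fractions, fractions[1:]))


# ---------------------------------------------------------------------------
# classify_association


def test_no_golgi_all_free():
    res = classify_association(_puncta([(0, 0), (100, 100)]), [], 1000.0)
    assert res.n_free == 2 and res.n_bound == 0
    assert res.states == ["FREE", "FREE"]


def test_zero_radius_all_free():
    res = classify_association(
        _puncta([(0.0, 0.0)]), _golgi([(0.0, 10.0)]), 0.0
    )
    assert res.n_bound == 0


def test_tie_breaks_to_lower_golgi_id():
    p = _puncta([(500.0, 0.0)])
    g = _golgi([(0.0, 0.0), (1000.0, 0.0)])  # equidistant at 500 nm
    res = classify_association(p, g, 1000.0)
    assert res.golgi_id[0] == 0


def test_bound_within_radius():
    p = _puncta([(0.0, 0.0), (0.0, 1500.0)])
    g = _golgi([(700.0, 0.0)])
    res = classify_association(p, g, 1000.0)
    assert res.golgi_id[0] == 0
    assert res.golgi_id[1] == -1
    assert res.free_to_bound_ratio == 1.0


def test_generator_ratio_recovery(small_scene):
    cfg, truth, ren = small_scene
    from erestrack.detection import detect_golgi, detect_puncta

    fr = ren.frame(0)
    p = detect_puncta(fr["eres"], cfg.pixel_size_nm)
    g = detect_golgi(fr["golgi"], cfg.pixel_size_nm)
    res = classify_association(p, g, 1000.0)
    true_bound = int(np.sum(truth.puncta_state[0] >= 0))
    assert res.n_bound == pytest.approx(true_bound, abs=2)


# ---------------------------------------------------------------------------
# ring_diameter


def test_exact_circle_ring():
    golgi = _golgi([(0.0, 0.0)])[0]
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    members = _puncta([(750 * np.cos(a), 750 * np.sin(a)) for a in angles])
    assert ring_diameter(golgi, members) == pytest.approx(1500.0)


def test_alternating_radii_arithmetic_mean():
    golgi = _golgi([(0.0, 0.0)])[0]
    radii = [700, 800] * 4
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    members = _puncta(
        [(r * np.cos(a), r * np.sin(a)) for r, a in zip(radii, angles)]
    )
    assert ring_diameter(golgi, members) == pytest.approx(1500.0)


def test_fewer_than_three_members_undefined():
    golgi = _golgi([(0.0, 0.0)])[0]
    assert np.isnan(ring_diameter(golgi, _puncta([(750.0, 0.0), (0.0, 750.0)])))


def test_generator_scene_ring_diameter():
    from erestrack.config import SceneConfig
    from erestrack.detection import detect_golgi, detect_puncta
    from erestrack.simulate import simulate_scene

    diams = []
    for seed in range(2):
        cfg = SceneConfig(
            field_size_px=(384, 384), n_golgi=3, n_puncta=24, frac_bound=1.0,
            n_frames=1, seed=seed,
        )
        truth, ren = simulate_scene(cfg)
        fr = ren.frame(0)
        p = detect_puncta(fr["eres"], cfg.pixel_size_nm)
        g = detect_golgi(fr["golgi"], cfg.pixel_size_nm)
        res = classify_association(p, g, 1000.0)
        diams += [d for d in res.rings["ring_diameter_nm"] if np.isfinite(d)]
    assert len(diams) >= 5
    assert abs(np.mean(diams) - 1500.0) < 100.0
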