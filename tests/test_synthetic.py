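"""Generator tests: network geometry, placement, dynamics, rendering."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import kstest
from skimage.measure import label as cc_label

from erestrack.config import SceneConfig
from erestrack.morphology import BG, SHEET, SHEET_RIM, TUBULE
from erestrack.simulate import (
    generate_er_network,
    place_objects,
    render,
    simulate_scene,
)


# ---------------------------------------------------------------------------
# network


def test_sheet_only_degenerate_scene():
    cfg = SceneConfig(
        field_size_px=(128, 128), n_golgi=0, n_sheets=1,
        lattice_spacing_px=40, seed=1,
    )
    net = generate_er_network(cfg)
    labels = set(np.unique(net.labels))
    assert SHEET in labels and SHEET_RIM in labels
    assert net.golgi_cavity_centers.shape == (0, 2)


def test_network_single_connected_component():
    net = generate_er_network(SceneConfig(seed=1))
    lab = cc_label(net.mask, connectivity=2)
    assert lab.max() == 1


def test_sheet_rim_near_background_distance_transform_oracle():
    # every sheet_rim pixel within 2 px of background, by brute-force EDT
    net = generate_er_network(SceneConfig(seed=2))
    edt_to_bg = ndimage.distance_transform_edt(net.mask)
    rim = net.labels == SHEET_RIM
    assert rim.any()
    assert np.all(edt_to_bg[rim] <= 2.0)


def test_cavities_at_least_n_golgi_and_large_enough():
    cfg = SceneConfig(seed=3)
    net = generate_er_network(cfg)
    assert len(net.cavities) >= cfg.n_golgi
    # each designated Golgi centre sits in enclosed background
    bg = cc_label(~net.mask, connectivity=1)
    border_labels = set(np.unique(np.concatenate(
        [bg[0], bg[-1], bg[:, 0], bg[:, -1]])))
    for x, y in net.golgi_cavity_centers:
        lab = bg[int(round(y)), int(round(x))]
        assert lab != 0 and lab not in border_labels


def test_impossible_cavity_count_fails():
    with pytest.raises(RuntimeError):
        generate_er_network(SceneConfig(field_size_px=(96, 96), n_golgi=8, seed=1))


def test_labels_partition_foreground():
    net = generate_er_network(SceneConfig(seed=4))
    assert np.array_equal(net.labels > 0, net.mask)
    assert set(np.unique(net.labels)) <= {BG, TUBULE, SHEET, SHEET_RIM}


# ---------------------------------------------------------------------------
# placement


def test_all_bound_forced_ring_geometry():
    cfg = SceneConfig(
        field_size_px=(256, 256), n_golgi=1, n_puncta=8, frac_bound=1.0, seed=5
    )
    net = generate_er_network(cfg)
    truth = place_objects(cfg, net)
    d_px = np.linalg.norm(truth.puncta_xy[0] - truth.golgi_xy[0, 0], axis=1)
    ring_r_px = cfg.ring_diameter_nm / 2 / cfg.pixel_size_nm
    assert len(d_px) == 8
    assert np.all(np.abs(d_px - ring_r_px) * cfg.pixel_size_nm < 150.0)


def test_bound_free_split_matches_fig_ratio():
    # frac_bound = 1/2.7 over 270 puncta -> 100 bound, 170 free
    cfg = SceneConfig(
        field_size_px=(768, 768), n_golgi=10, n_puncta=270,
        frac_bound=1 / 2.7, seed=6,
    )
    net = generate_er_network(cfg)
    truth = place_objects(cfg, net)
    n_bound = int(np.sum(truth.puncta_state[0] >= 0))
    assert n_bound == 100
    assert truth.n_puncta - n_bound == 170


def test_free_subdomain_multinomial_oracle():
    # placement draws subdomain counts with rng.multinomial; an independent
    # generator with the same child seed reproduces them exactly
    from erestrack.simulate import stage_rngs

    cfg = SceneConfig(
        field_size_px=(512, 512), n_golgi=0, frac_bound=0.0, n_puncta=120,
        free_subdomain_probs=(0.5, 0.4, 0.1), seed=9,
    )
    rngs = stage_rngs(cfg.seed)
    net = generate_er_network(cfg, rngs["network"])
    truth = place_objects(cfg, net, rngs["placement"])

    oracle = stage_rngs(cfg.seed)["placement"]
    expected = oracle.multinomial(120, cfg.free_subdomain_probs)
    got = [
        int(np.sum(truth.puncta_subdomain0 == code))
        for code in (TUBULE, SHEET_RIM, SHEET)
    ]
    assert got == list(expected)


def test_free_puncta_sit_on_their_subdomain():
    cfg = SceneConfig(n_golgi=0, frac_bound=0.0, n_puncta=60, seed=10)
    net = generate_er_network(cfg)
    truth = place_objects(cfg, net)
    for (x, y), code in zip(truth.puncta_xy[0], truth.puncta_subdomain0):
        assert net.labels[int(round(y)), int(round(x))] == code


def test_zero_pixel_subdomain_with_positive_prob_fails():
    # a lone disc has sheet and rim pixels but no tubule
    from skimage.draw import disk as draw_disk

    from erestrack.morphology import classify_subdomains
    from erestrack.simulate import NetworkTruth

    mask = np.zeros((96, 96), dtype=bool)
    rr, cc = draw_disk((48, 48), 15)
    mask[rr, cc] = True
    cfg = SceneConfig(
        field_size_px=(96, 96), n_golgi=0, frac_bound=0.0, n_puncta=5,
        free_subdomain_probs=(1.0, 0.0, 0.0), seed=1,
    )
    sub = classify_subdomains(mask, cfg.pixel_size_nm)
    assert not np.any(sub.labels == TUBULE)
    net = NetworkTruth(
        mask=mask, labels=sub.labels, cavities=[],
        golgi_cavity_centers=np.empty((0, 2)),
    )
    with pytest.raises(ValueError):
        place_objects(cfg, net)


# ---------------------------------------------------------------------------
# dynamics


def _kinetic_scene(**overrides):
    kwargs = dict(
        field_size_px=(320, 320),
        n_golgi=2,
        n_puncta=6,
        frac_bound=1.0,
        n_frames=50,
        seed=20,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


def test_zero_rates_no_events_states_constant():
    cfg = _kinetic_scene(k_capture_per_s=0.0, k_release_per_s=0.0)
    truth, _ = simulate_scene(cfg)
    assert truth.events == []
    assert np.all(truth.puncta_state == truth.puncta_state[0])


def test_inhibited_mode_no_net_drift():
    cfg = _kinetic_scene(cytoskeleton_inhibited=True, n_frames=100)
    truth, _ = simulate_scene(cfg)
    disp = truth.golgi_xy[-1] - truth.golgi_xy[0]
    mean_disp_nm = np.linalg.norm(disp.mean(axis=0)) * cfg.pixel_size_nm
    # Brownian-only: rms of the ensemble mean ~ sqrt(2 D T / n_golgi)
    assert mean_disp_nm < 1000.0


def test_streaming_produces_drift():
    cfg = _kinetic_scene(n_frames=100, streaming_speed_nm_s=1000.0)
    truth, _ = simulate_scene(cfg)
    disp = (truth.golgi_xy[-1] - truth.golgi_xy[0]) * cfg.pixel_size_nm
    assert np.linalg.norm(disp.mean(axis=0)) > 5000.0  # ~10 s at 1 um/s


def test_bound_distance_invariant():
    cfg = _kinetic_scene(n_frames=60, k_release_per_s=1 / 50)
    truth, _ = simulate_scene(cfg)
    ring_r_nm = cfg.ring_diameter_nm / 2
    for t in range(truth.n_frames):
        for i in range(truth.n_puncta):
            g = truth.puncta_state[t, i]
            if g >= 0:
                d = np.linalg.norm(
                    truth.puncta_xy[t, i] - truth.golgi_xy[t, g]
                ) * cfg.pixel_size_nm
                assert abs(d - ring_r_nm) < 150.0


def test_event_log_alternates_per_pair():
    cfg = _kinetic_scene(
        n_frames=1500,
        k_capture_per_s=0.2,
        k_release_per_s=0.2,
        capture_radius_nm=3000.0,
        diffusion_coeff_nm2_s=400.0,
        cytoskeleton_inhibited=True,
    )
    truth, _ = simulate_scene(cfg)
    ev = truth.event_table()
    assert len(ev) > 20
    for (punctum, _golgi), grp in ev.groupby(["punctum_id", "golgi_id"]):
        kinds = list(grp.sort_values("frame")["kind"])
        for a, b in zip(kinds, kinds[1:]):
            assert a != b, "capture/release must alternate per pair"


def test_release_waiting_times_exponential():
    # many bound puncta, no recapture: pure exponential clock at k_release
    k = 1 / 35
    cfg = SceneConfig(
        field_size_px=(768, 768), n_golgi=12, n_puncta=600, frac_bound=1.0,
        n_frames=1200, k_release_per_s=k, k_capture_per_s=0.0,
        cytoskeleton_inhibited=True, min_puncta_separation_nm=10.0,
        seed=31,
    )
    truth, _ = simulate_scene(cfg)
    ev = truth.event_table()
    waits = ev[ev["kind"] == "release"]["time_s"].to_numpy()
    assert len(waits) >= 500
    # censored draw: condition the reference exponential on t <= T
    T = cfg.n_frames * cfg.frame_interval_s
    stat = kstest(waits, lambda x: (1 - np.exp(-k * x)) / (1 - np.exp(-k * T)))
    assert stat.pvalue > 0.01


def test_truth_determinism():
    cfg = _kinetic_scene(k_capture_per_s=0.1, k_release_per_s=0.1)
    t1, _ = simulate_scene(cfg)
    t2, _ = simulate_scene(cfg)
    assert np.array_equal(t1.puncta_xy, t2.puncta_xy)
    assert np.array_equal(t1.golgi_xy, t2.golgi_xy)
    assert t1.events == t2.events


# ---------------------------------------------------------------------------
# rendering


def test_render_deterministic_bit_identical():
    cfg = _kinetic_scene(n_frames=2)
    truth, ren = simulate_scene(cfg)
    a = render(cfg, truth)
    b = render(cfg, truth)
    assert np.array_equal(a.data, b.data)


def test_streamed_frames_equal_batch():
    cfg = _kinetic_scene(n_frames=3)
    _, ren = simulate_scene(cfg)
    series = ren.series()
    for t in range(3):
        fr = ren.frame(t)
        for c, name in enumerate(ren.channel_names):
            assert np.array_equal(series.data[c, t], fr[name].astype(np.float32))


def test_noiseless_peak_at_true_centroid():
    cfg = SceneConfig(
        field_size_px=(128, 128), n_golgi=0, frac_bound=0.0, n_puncta=1,
        n_frames=1, read_noise_sd=0.0, seed=2,
    )
    truth, ren = simulate_scene(cfg)
    img = ren.frame(0, noise=False)["eres"]
    peak = np.unravel_index(np.argmax(img), img.shape)
    x, y = truth.puncta_xy[0, 0]
    assert abs(peak[1] - x) <= 0.6 and abs(peak[0] - y) <= 0.6


def test_rendered_fwhm_matches_closed_form():
    # 400 nm FWHM at 65 nm/px -> measured FWHM 400/65 = 6.15 px
    cfg = SceneConfig(
        field_size_px=(128, 128), n_golgi=0, frac_bound=0.0, n_puncta=1,
        n_frames=1, punctum_fwhm_nm=(400.0, 400.0), seed=2,
    )
    truth, ren = simulate_scene(cfg)
    img = ren.frame(0, noise=False)["eres"] - cfg.background_photons
    x, y = truth.puncta_xy[0, 0]
    row = img[int(round(y))]
    half = row.max() / 2
    above = np.where(row >= half)[0]
    measured = above[-1] - above[0] + 1  # integer-sampled width
    assert abs(measured - 400 / 65) <= 1.0


def test_rendered_values_non_negative():
    cfg = _kinetic_scene(n_frames=2, read_noise_sd=5.0)
    _, ren = simulate_scene(cfg)
    assert np.all(ren.frame(0)["eres"] >= 0)
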