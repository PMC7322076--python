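# Reference scenario bundle: one scene block per reproduced quantity.
# Every scenario shares the imaging constants (65 nm/px, 100 ms/frame,
# 300-500 nm puncta, 1.5 um beaded rings) and sets only what its
# quantity needs. Used by scripts/acceptance.py and the acceptance tests.

common: &common
  pixel_size_nm: 65.0
  frame_interval_s: 0.1
  punctum_fwhm_nm: [300.0, 500.0]
  ring_diameter_nm: 1500.0
  golgi_diameter_nm: 1000.0
  cavity_diameter_nm: 2600.0

scenarios:
  # object-based colocalization: 95% of channel-B puncta sit on channel-A puncta
  coloc:
    scene:
      <<: *common
      field_size_px: [512, 512]
      n_frames: 1
      n_golgi: 0
      frac_bound: 0.0
      n_puncta: 60
      coloc_fraction: 0.95
      channels: [eres, er]
    n_replicates: 20
    match_radius_nm: 300.0

  # Golgi-free vs Golgi-associated: bound fraction 1/2.7 -> free:bound = 1.7
  association:
    scene:
      <<: *common
      field_size_px: [512, 512]
      n_frames: 1
      n_golgi: 5
      n_puncta: 54
      frac_bound: 0.37037037037037035   # 1/2.7
      channels: [eres, golgi]
    n_replicates: 20
    assoc_radius_nm: 1000.0

  # free puncta on ER subdomains: (tubule, sheet_rim, sheet) = (0.5, 0.4, 0.1)
  subdomains:
    scene:
      <<: *common
      field_size_px: [512, 512]
      n_frames: 1
      n_golgi: 0
      frac_bound: 0.0
      n_puncta: 100
      free_subdomain_probs: [0.5, 0.4, 0.1]
      channels: [eres, er]
    n_replicates: 9
    subdomain_params:
      tubule_max_width_nm: 260.0
      rim_band_nm: 195.0      # deconvolved sheet boundaries carry ~1 px slack
      snap_radius_nm: 400.0

  # beaded rings at 1.5 um around every Golgi
  rings:
    scene:
      <<: *common
      field_size_px: [512, 512]
      n_frames: 1
      n_golgi: 5
      n_puncta: 30            # 6 ring members per Golgi
      frac_bound: 1.0
      channels: [eres, golgi]
    n_replicates: 5

  # capture/release kinetics at k = 1/35 per s; streaming plays no role in
  # the cycling (it is cytoskeleton-independent), so the kinetics scene
  # runs without drift to keep every Golgi resident in its cavity for the
  # whole 200-s observation. Three 10-Golgi movies give 30 observed Golgi.
  kinetics:
    scene:
      <<: *common
      field_size_px: [384, 384]
      cavity_diameter_nm: 3000.0
      n_frames: 2000            # 200 s at 0.1 s/frame
      n_golgi: 10
      n_puncta: 28
      frac_bound: 0.475         # near the cycling steady state
      k_capture_per_s: 0.02857142857142857   # 1/35
      k_release_per_s: 0.02857142857142857
      cytoskeleton_inhibited: true
      diffusion_coeff_nm2_s: 400.0
      golgi_diffusion_coeff_nm2_s: 200.0
      capture_radius_nm: 3600.0
      channels: [eres, golgi]
    n_replicates: 3

  # cytoskeleton-inhibitor mode: no streaming, capture still occurs
  inhibited:
    scene:
      <<: *common
      field_size_px: [384, 384]
      cavity_diameter_nm: 3000.0
      n_frames: 400
      n_golgi: 6
      n_puncta: 20
      frac_bound: 0.5
      k_capture_per_s: 0.02857142857142857
      k_release_per_s: 0.02857142857142857
      cytoskeleton_inhibited: true
      diffusion_coeff_nm2_s: 400.0
      golgi_diffusion_coeff_nm2_s: 200.0
      capture_radius_nm: 3600.0
      channels: [eres, golgi]
    n_replicates: 1
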