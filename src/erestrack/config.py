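"""Configuration dataclasses for the simulator and every analysis stage.

All physical parameters are expressed in nanometres and seconds; image
coordinates use ``x = column``, ``y = row`` with pixel centres at integer
coordinates and the origin at the top-left pixel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SceneConfig",
    "DetectionParams",
    "SegmentationParams",
    "SubdomainParams",
    "AssociationParams",
    "TrackingParams",
    "EventParams",
    "MotionParams",
    "RunConfig",
    "load_run_config",
    "dump_run_config",
]

FWHM_PER_SIGMA = 2.355  # 2 * sqrt(2 ln 2)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass
class SceneConfig:
    """Parameters of one synthetic cortical-ER scene.

    Defaults describe the reference scenario: a 512x512 px field at
    65 nm/px imaged at 100-ms intervals, diffraction-limited puncta with
    apparent sizes of 300-500 nm, Golgi blobs sitting in ER-network
    cavities and surrounded by beaded rings of bound puncta 1.5 um in
    diameter.
    """

    field_size_px: tuple[int, int] = (512, 512)  # (height, width)
    pixel_size_nm: float = 65.0
    frame_interval_s: float = 0.1
    n_frames: int = 20

    # objects
    n_golgi: int = 6
    golgi_diameter_nm: float = 1000.0
    ring_diameter_nm: float = 1500.0
    cavity_diameter_nm: float = 2600.0
    punctum_fwhm_nm: tuple[float, float] = (300.0, 500.0)
    n_puncta: int = 60
    frac_bound: float = 1.0 / 2.7
    free_subdomain_probs: tuple[float, float, float] = (0.5, 0.4, 0.1)
    min_puncta_separation_nm: float = 600.0
    coloc_fraction: float | None = None  # second puncta channel if set

    # motion / kinetics
    streaming_speed_nm_s: float = 1000.0
    diffusion_coeff_nm2_s: float = 1.0e4
    golgi_diffusion_coeff_nm2_s: float = 2.0e3
    k_capture_per_s: float = 0.0
    k_release_per_s: float = 0.0
    capture_radius_nm: float | None = None  # default: ring radius
    escape_speed_nm_s: float = 1000.0
    cytoskeleton_inhibited: bool = False

    # network geometry (pixels)
    tubule_width_px: int = 3
    sheet_radius_px_range: tuple[int, int] = (8, 13)
    n_sheets: int = 10
    lattice_spacing_px: int = 42

    # optics / noise
    psf_sigma_nm: float = 130.0
    photon_scale: float = 200.0
    background_photons: float = 2.0
    read_noise_sd: float = 2.0
    channels: tuple[str, ...] = ("eres", "golgi", "er")

    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 32 or w < 32:
            raise ValueError("field_size_px must be at least 32x32")
        for name in (
            "pixel_size_nm",
            "frame_interval_s",
            "golgi_diameter_nm",
            "ring_diameter_nm",
            "cavity_diameter_nm",
            "psf_sigma_nm",
        ):
            _positive(name, getattr(self, name))
        if not 0.0 <= self.frac_bound <= 1.0:
            raise ValueError("frac_bound must lie in [0, 1]")
        probs = self.free_subdomain_probs
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("free_subdomain_probs must be non-negative and sum to 1")
        if self.coloc_fraction is not None and not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        lo, hi = self.punctum_fwhm_nm
        if not (0 < lo <= hi):
            raise ValueError("punctum_fwhm_nm must be an increasing positive range")
        if self.ring_diameter_nm <= self.golgi_diameter_nm:
            raise ValueError("ring_diameter_nm must exceed golgi_diameter_nm")
        if self.cavity_diameter_nm < self.ring_diameter_nm:
            raise ValueError("cavity_diameter_nm must be >= ring_diameter_nm")
        for name in ("k_capture_per_s", "k_release_per_s", "streaming_speed_nm_s",
                     "diffusion_coeff_nm2_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- derived quantities ------------------------------------------------
    @property
    def ring_radius_px(self) -> float:
        return self.ring_diameter_nm / 2.0 / self.pixel_size_nm

    @property
    def cavity_radius_px(self) -> float:
        return self.cavity_diameter_nm / 2.0 / self.pixel_size_nm

    @property
    def capture_radius(self) -> float:
        """Capture eligibility radius in nm (defaults to the ring radius)."""
        if self.capture_radius_nm is not None:
            return self.capture_radius_nm
        return self.ring_diameter_nm / 2.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def streaming_speed(self) -> float:
        return 0.0 if self.cytoskeleton_inhibited else self.streaming_speed_nm_s


@dataclass
class DetectionParams:
    fwhm_nm_range: tuple[float, float] = (300.0, 500.0)
    n_scales: int = 3
    peak_threshold_mad: float = 8.0
    min_separation_nm: float = 400.0
    refine_window_sigmas: float = 2.0


@dataclass
class SegmentationParams:
    smoothing_sigma_nm: float = 65.0
    deconv_sigma_nm: float = 130.0  # PSF width for deconvolution; 0 disables
    deconv_iterations: int = 40
    threshold_method: str = "local_fraction"  # local_fraction | otsu | quantile
    block_size_px: int = 51
    local_max_fraction: float = 0.45
    quantile: float = 0.8
    min_object_area_px: int = 25


@dataclass
class SubdomainParams:
    tubule_max_width_nm: float = 260.0
    rim_band_nm: float = 130.0
    min_cavity_diameter_nm: float = 1500.0
    snap_radius_nm: float = 400.0


@dataclass
class AssociationParams:
    assoc_radius_nm: float = 1000.0
    match_radius_nm: float = 300.0
    min_ring_members: int = 3
    min_golgi_area_nm2: float = 1.5e5
    golgi_threshold_method: str = "otsu"  # otsu | quantile
    golgi_quantile: float = 0.995


@dataclass
class TrackingParams:
    max_disp_nm: float = 400.0
    max_gap: int = 1


@dataclass
class MotionParams:
    min_track_frames: int = 10
    straightness_threshold: float = 0.5
    min_speed_nm_s: float = 300.0


@dataclass
class EventParams:
    assoc_radius_nm: float = 1000.0
    min_dwell_frames: int = 3
    window_s: float = 10.0


@dataclass
class RunConfig:
    """Full pipeline configuration: one scene (or input movie) plus one
    parameter block per analysis stage."""

    scene: SceneConfig | None = None
    input_movie: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    subdomains: SubdomainParams = field(default_factory=SubdomainParams)
    association: AssociationParams = field(default_factory=AssociationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    motion: MotionParams = field(default_factory=MotionParams)
    events: EventParams = field(default_factory=EventParams)
    out_dir: str = "results"
    seed: int | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.scene is None and self.input_movie is None:
            raise ValueError("RunConfig needs either a scene or an input movie")


# ---------------------------------------------------------------------------
# YAML round-trip

_STAGE_TYPES: dict[str, type] = {
    "scene": SceneConfig,
    "detection": DetectionParams,
    "segmentation": SegmentationParams,
    "subdomains": SubdomainParams,
    "association": AssociationParams,
    "tracking": TrackingParams,
    "motion": MotionParams,
    "events": EventParams,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: dict[str, Any]) -> Any:
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def run_config_to_dict(config: RunConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, value in (
        ("scene", config.scene),
        ("input_movie", config.input_movie),
    ):
        if value is not None:
            out[name] = _to_plain(value)
    for name in ("detection", "segmentation", "subdomains", "association",
                 "tracking", "motion", "events"):
        out[name] = _to_plain(getattr(config, name))
    out["out_dir"] = config.out_dir
    out["seed"] = config.seed
    out["verbosity"] = config.verbosity
    return out


def run_config_from_dict(data: dict[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for name, cls in _STAGE_TYPES.items():
        if name in data and data[name] is not None:
            kwargs[name] = _from_plain(cls, data[name])
    for name in ("input_movie", "out_dir", "seed", "verbosity"):
        if name in data and data[name] is not None:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(run_config_to_dict(config), fh, sort_keys=False)


def scene_from_dict(data: dict[str, Any]) -> SceneConfig:
    return _from_plain(SceneConfig, data)
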