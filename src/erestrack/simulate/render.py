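"""Forward optics: ground truth -> noisy fluorescence frames.

Each puncta channel is a sum of Gaussian spots (sigma = FWHM / 2.355),
Golgi are larger Gaussian blobs, and the ER channel is the network mask
convolved with the PSF. Pixel values are scaled to expected photon
counts, Poisson sampled, and read noise is added.

Frames can be rendered one at a time (``Renderer.frame``) so long movies
never need to be held in memory; rendering frame t is bit-identical
whether done in isolation or as part of the full series.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..config import FWHM_PER_SIGMA, SceneConfig
from ..frames import FrameSeries
from .truth import GroundTruth

__all__ = ["Renderer", "render"]


def add_gaussian_spot(
    img: np.ndarray, x: float, y: float, sigma_px: float, amplitude: float
) -> None:
    """Accumulate one Gaussian blob into ``img`` (in place)."""
    h, w = img.shape
    half = int(np.ceil(4.0 * sigma_px))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2)
    )


class Renderer:
    """Renders a GroundTruth scene frame by frame, deterministically."""

    def __init__(self, config: SceneConfig, truth: GroundTruth, seed: int | None = None):
        self.config = config
        self.truth = truth
        base = config.seed if seed is None else seed
        # one child seed per frame so streaming == batch rendering
        self._frame_seeds = np.random.SeedSequence((base, 0xC0FFEE)).spawn(
            truth.n_frames
        )
        self._er_base: np.ndarray | None = None

    @property
    def channel_names(self) -> tuple[str, ...]:
        names = list(self.config.channels)
        if self.truth.coloc is not None and "copii" not in names:
            names.append("copii")
        return tuple(names)

    def _er_ideal(self) -> np.ndarray:
        if self._er_base is None:
            cfg = self.config
            base = ndimage.gaussian_filter(
                self.truth.network.mask.astype(float), cfg.psf_sigma_px
            )
            self._er_base = 0.5 * cfg.photon_scale * base
        return self._er_base

    def _ideal_channel(self, name: str, t: int) -> np.ndarray:
        cfg = self.config
        h, w = self.truth.network.mask.shape
        img = np.zeros((h, w))
        if name == "eres":
            sigmas = self.truth.puncta_fwhm_nm / FWHM_PER_SIGMA / cfg.pixel_size_nm
            for (x, y), s in zip(self.truth.puncta_xy[t], sigmas):
                add_gaussian_spot(img, x, y, s, cfg.photon_scale)
        elif name == "copii":
            coloc = self.truth.coloc
            if coloc is not None:
                sigmas = coloc.fwhm_nm / FWHM_PER_SIGMA / cfg.pixel_size_nm
                for (x, y), s in zip(coloc.xy_px, sigmas):
                    add_gaussian_spot(img, x, y, s, cfg.photon_scale)
        elif name == "golgi":
            sigma = cfg.golgi_diameter_nm / FWHM_PER_SIGMA / cfg.pixel_size_nm
            for x, y in self.truth.golgi_xy[t]:
                add_gaussian_spot(img, x, y, sigma, 3.0 * cfg.photon_scale)
        elif name == "er":
            img = self._er_ideal().copy()
        else:
            raise KeyError(f"unknown channel {name!r}")
        return img

    def frame(self, t: int, noise: bool = True) -> dict[str, np.ndarray]:
        """Render all channels of frame ``t`` as photon-count images."""
        cfg = self.config
        rng = np.random.default_rng(self._frame_seeds[t])
        out = {}
        for name in self.channel_names:
            ideal = self._ideal_channel(name, t) + cfg.background_photons
            if noise:
                img = rng.poisson(ideal).astype(float)
                if cfg.read_noise_sd > 0:
                    img += rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
                img = np.clip(img, 0.0, None)
            else:
                img = ideal
            out[name] = img
        return out

    def series(self, noise: bool = True) -> FrameSeries:
        names = self.channel_names
        h, w = self.truth.network.mask.shape
        data = np.zeros((len(names), self.truth.n_frames, h, w), dtype=np.float32)
        for t in range(self.truth.n_frames):
            fr = self.frame(t, noise=noise)
            for c, name in enumerate(names):
                data[c, t] = fr[name]
        return FrameSeries(
            data=data,
            channel_names=names,
            pixel_size_nm=self.config.pixel_size_nm,
            frame_interval_s=self.config.frame_interval_s,
        )


def render(
    config: SceneConfig, truth: GroundTruth, noise: bool = True
) -> FrameSeries:
    """Render the whole scene to a FrameSeries."""
    if truth.n_frames != config.n_frames:
        raise ValueError("GroundTruth frame count does not match config.n_frames")
    return Renderer(config, truth).series(noise=noise)
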