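"""Diffraction-limited spot and Golgi-blob detection.

Puncta are found as multiscale Laplacian-of-Gaussian maxima with the
threshold expressed in robust (median-absolute-deviation) units of the
LoG response, non-maximum suppression at a physical separation, and
subpixel refinement by intensity-weighted centroid. The apparent size
(FWHM) comes from the best-responding scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects

from .config import FWHM_PER_SIGMA, AssociationParams, DetectionParams

__all__ = [
    "Punctum",
    "GolgiObject",
    "detect_puncta",
    "detect_golgi",
    "puncta_to_dataframe",
    "golgi_to_dataframe",
]


@dataclass
class Punctum:
    """One detected diffraction-limited spot."""

    frame_index: int
    channel: str
    x_px: float
    y_px: float
    x_nm: float
    y_nm: float
    fwhm_nm: float
    peak_intensity: float
    id: int | None = None

    @property
    def xy_nm(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm])


@dataclass
class GolgiObject:
    """One detected Golgi blob."""

    frame_index: int
    x_px: float
    y_px: float
    x_nm: float
    y_nm: float
    equivalent_diameter_nm: float
    area_px: int
    id: int | None = None

    @property
    def xy_nm(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm])


def _refine_centroid(
    img: np.ndarray, row: int, col: int, half: int
) -> tuple[float, float]:
    """Intensity-weighted centroid in a window, after local background
    subtraction; falls back to the peak pixel for degenerate windows."""
    h, w = img.shape
    r0, r1 = max(row - half, 0), min(row + half + 1, h)
    c0, c1 = max(col - half, 0), min(col + half + 1, w)
    win = img[r0:r1, c0:c1].astype(float)
    win = win - np.median(win)
    win[win < 0] = 0.0
    total = win.sum()
    if total <= 0:
        return float(col), float(row)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    return float((xx * win).sum() / total), float((yy * win).sum() / total)


def detect_puncta(
    frame: np.ndarray,
    pixel_size_nm: float,
    params: DetectionParams | None = None,
    frame_index: int = 0,
    channel: str = "eres",
) -> list[Punctum]:
    """Detect puncta in one single-channel frame."""
    if params is None:
        params = DetectionParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_puncta expects a single 2-D frame")
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite pixels")
    if img.size == 0 or img.max() <= img.min():
        return []

    lo, hi = params.fwhm_nm_range
    if params.n_scales == 1:
        sigmas_px = np.array([(lo + hi) / 2.0]) / FWHM_PER_SIGMA / pixel_size_nm
    else:
        sigmas_px = (
            np.linspace(lo, hi, params.n_scales) / FWHM_PER_SIGMA / pixel_size_nm
        )
    # scale-normalized LoG, sign-flipped so bright spots respond positively;
    # float32 filtering: ~2x faster, relative error ~1e-2 of the response
    img_f = img.astype(np.float32)
    responses = np.stack(
        [
            -(s**2) * ndimage.gaussian_laplace(img_f, s, truncate=3.0)
            for s in sigmas_px
        ]
    )
    resp_max = responses.max(axis=0)

    med = np.median(resp_max)
    mad = 1.4826 * np.median(np.abs(resp_max - med)) + 1e-12
    thr = med + params.peak_threshold_mad * mad

    peaks = peak_local_max(
        resp_max, min_distance=1, threshold_abs=thr, exclude_border=False
    )
    if len(peaks) == 0:
        return []

    # non-maximum suppression at min_separation_nm; ties broken by higher
    # response then scan order (stable sort keeps scan order within ties)
    resp_at = resp_max[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-resp_at, kind="stable")
    min_sep_px = params.min_separation_nm / pixel_size_nm
    kept: list[int] = []
    kept_yx: list[np.ndarray] = []
    for k in order:
        p = peaks[k].astype(float)
        if kept_yx and np.min(
            np.linalg.norm(np.array(kept_yx) - p, axis=1)
        ) < min_sep_px:
            continue
        kept.append(k)
        kept_yx.append(p)

    out: list[Punctum] = []
    for k in kept:
        row, col = int(peaks[k, 0]), int(peaks[k, 1])
        scale_idx = int(np.argmax(responses[:, row, col]))
        sigma_best = sigmas_px[scale_idx]
        half = int(np.ceil(params.refine_window_sigmas * sigma_best))
        x, y = _refine_centroid(img, row, col, half)
        x = float(np.clip(x, 0, img.shape[1] - 1))
        y = float(np.clip(y, 0, img.shape[0] - 1))
        out.append(
            Punctum(
                frame_index=frame_index,
                channel=channel,
                x_px=x,
                y_px=y,
                x_nm=x * pixel_size_nm,
                y_nm=y * pixel_size_nm,
                fwhm_nm=float(FWHM_PER_SIGMA * sigma_best * pixel_size_nm),
                peak_intensity=float(img[row, col]),
            )
        )
    return out


def detect_golgi(
    frame: np.ndarray,
    pixel_size_nm: float,
    params: AssociationParams | None = None,
    frame_index: int = 0,
) -> list[GolgiObject]:
    """Detect Golgi blobs by thresholding and connected components."""
    if params is None:
        params = AssociationParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_golgi expects a single 2-D frame")
    if img.size == 0 or img.max() <= img.min():
        return []

    sm = ndimage.gaussian_filter(img, 1.0)
    med = np.median(sm)
    mad = 1.4826 * np.median(np.abs(sm - med)) + 1e-12
    if params.golgi_threshold_method == "otsu":
        thr = threshold_otsu(sm)
    elif params.golgi_threshold_method == "quantile":
        thr = np.quantile(sm, params.golgi_quantile)
    else:
        raise ValueError(
            f"unknown golgi_threshold_method {params.golgi_threshold_method!r}"
        )
    # an Otsu split of pure noise sits near the median: nothing to detect
    if thr <= med + 5.0 * mad:
        return []

    min_area_px = max(int(params.min_golgi_area_nm2 / pixel_size_nm**2), 1)
    mask = remove_small_objects(sm > thr, max_size=min_area_px - 1)
    lab = cc_label(mask, connectivity=2)
    out: list[GolgiObject] = []
    for region in regionprops(lab, intensity_image=img):
        cy, cx = region.centroid_weighted
        out.append(
            GolgiObject(
                frame_index=frame_index,
                x_px=float(cx),
                y_px=float(cy),
                x_nm=float(cx) * pixel_size_nm,
                y_nm=float(cy) * pixel_size_nm,
                equivalent_diameter_nm=float(
                    region.equivalent_diameter_area * pixel_size_nm
                ),
                area_px=int(region.area),
            )
        )
    out.sort(key=lambda g: (g.y_px, g.x_px))
    for i, g in enumerate(out):
        g.id = i
    return out


def puncta_to_dataframe(puncta: list[Punctum]) -> pd.DataFrame:
    cols = ["frame", "channel", "x_px", "y_px", "x_nm", "y_nm", "fwhm_nm", "intensity"]
    if not puncta:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        {
            "frame": [p.frame_index for p in puncta],
            "channel": [p.channel for p in puncta],
            "x_px": [p.x_px for p in puncta],
            "y_px": [p.y_px for p in puncta],
            "x_nm": [p.x_nm for p in puncta],
            "y_nm": [p.y_nm for p in puncta],
            "fwhm_nm": [p.fwhm_nm for p in puncta],
            "intensity": [p.peak_intensity for p in puncta],
        }
    )


def golgi_to_dataframe(golgi: list[GolgiObject]) -> pd.DataFrame:
    cols = ["frame", "golgi_id", "x_px", "y_px", "x_nm", "y_nm",
            "equivalent_diameter_nm", "area_px"]
    if not golgi:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(
        {
            "frame": [g.frame_index for g in golgi],
            "golgi_id": [g.id for g in golgi],
            "x_px": [g.x_px for g in golgi],
            "y_px": [g.y_px for g in golgi],
            "x_nm": [g.x_nm for g in golgi],
            "y_nm": [g.y_nm for g in golgi],
            "equivalent_diameter_nm": [g.equivalent_diameter_nm for g in golgi],
            "area_px": [g.area_px for g in golgi],
        }
    )
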