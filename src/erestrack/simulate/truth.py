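"""Ground-truth record kept by the generator.

Everything downstream (detection, segmentation, association, tracking,
event statistics) is validated against this record, so it stores per-frame
true positions, binding states and the full capture/release event log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ..morphology import CavityRegion

# punctum state codes used in the per-frame state array
FREE = -1
TRANSIT = -2  # moving between the ER and a Golgi ring (counts as free)

SUBDOMAIN_NAMES = {0: "background", 1: "tubule", 2: "sheet", 3: "sheet_rim"}


@dataclass
class NetworkTruth:
    """True ER geometry: binary mask, subdomain labels, cavities."""

    mask: np.ndarray  # bool (H, W)
    labels: np.ndarray  # uint8 (H, W): 0 bg, 1 tubule, 2 sheet, 3 sheet_rim
    cavities: list[CavityRegion]
    golgi_cavity_centers: np.ndarray  # (n_golgi, 2) float px, (x, y)


@dataclass
class ColocTruth:
    """Second puncta channel for object-based colocalization scenes."""

    xy_px: np.ndarray  # (n_b, 2)
    fwhm_nm: np.ndarray  # (n_b,)
    on_a: np.ndarray  # bool (n_b,): placed on a channel-A punctum
    a_index: np.ndarray  # int (n_b,): which A punctum, -1 if not on one


@dataclass
class GroundTruth:
    """Full truth for one simulated scene.

    Positions are stored in pixels (x = column, y = row, float, pixel
    centres at integers); convert with ``pixel_size_nm``.
    """

    pixel_size_nm: float
    frame_interval_s: float
    network: NetworkTruth
    golgi_xy: np.ndarray  # (T, G, 2) float px
    puncta_xy: np.ndarray  # (T, N, 2) float px
    puncta_state: np.ndarray  # (T, N) int: FREE, TRANSIT or golgi id
    puncta_fwhm_nm: np.ndarray  # (N,)
    puncta_subdomain0: np.ndarray  # (N,) uint8 label at placement (0 if bound)
    events: list[dict] = field(default_factory=list)
    coloc: ColocTruth | None = None

    @property
    def n_frames(self) -> int:
        return self.puncta_xy.shape[0]

    @property
    def n_golgi(self) -> int:
        return self.golgi_xy.shape[1]

    @property
    def n_puncta(self) -> int:
        return self.puncta_xy.shape[1]

    # -- tabular views -----------------------------------------------------
    def puncta_table(self) -> pd.DataFrame:
        t_idx, p_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_puncta), indexing="ij"
        )
        state = self.puncta_state.ravel()
        return pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "punctum_id": p_idx.ravel(),
                "x_px": self.puncta_xy[..., 0].ravel(),
                "y_px": self.puncta_xy[..., 1].ravel(),
                "x_nm": self.puncta_xy[..., 0].ravel() * self.pixel_size_nm,
                "y_nm": self.puncta_xy[..., 1].ravel() * self.pixel_size_nm,
                "state": np.where(state >= 0, "BOUND", "FREE"),
                "golgi_id": np.where(state >= 0, state, -1),
                "fwhm_nm": np.tile(self.puncta_fwhm_nm, self.n_frames),
                "subdomain": [
                    SUBDOMAIN_NAMES.get(s, "background")
                    for s in np.tile(self.puncta_subdomain0, self.n_frames)
                ],
            }
        )

    def golgi_table(self) -> pd.DataFrame:
        t_idx, g_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_golgi), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "golgi_id": g_idx.ravel(),
                "x_px": self.golgi_xy[..., 0].ravel(),
                "y_px": self.golgi_xy[..., 1].ravel(),
                "x_nm": self.golgi_xy[..., 0].ravel() * self.pixel_size_nm,
                "y_nm": self.golgi_xy[..., 1].ravel() * self.pixel_size_nm,
            }
        )

    def event_table(self) -> pd.DataFrame:
        if not self.events:
            return pd.DataFrame(
                columns=["frame", "time_s", "kind", "golgi_id", "punctum_id"]
            )
        return pd.DataFrame(self.events)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.puncta_table().to_csv(out / "puncta_truth.csv", index=False)
        self.golgi_table().to_csv(out / "golgi_truth.csv", index=False)
        self.event_table().to_csv(out / "events_truth.csv", index=False)
        tifffile.imwrite(out / "er_labels_truth.tif", self.network.labels)
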