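"""Object-based colocalization and Golgi-association classification.

Colocalization is an optimal one-to-one assignment on the thresholded
distance matrix: it maximizes the number of pairs within the match
radius and, among such matchings, minimizes the summed pair distance.
Association to Golgi is nearest-centroid with a distance cutoff, with
beaded-ring diameter estimated from the ring members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import AssociationParams
from .detection import GolgiObject, Punctum
from .stats import ProportionEstimate, proportion_ci

__all__ = [
    "MatchResult",
    "AssociationResult",
    "colocalize",
    "classify_association",
    "ring_diameter",
]

_BIG = 1.0e12


def _as_xy_nm(objs) -> np.ndarray:
    if isinstance(objs, np.ndarray):
        return objs.reshape(-1, 2).astype(float)
    return np.array(
        [[o.x_nm, o.y_nm] for o in objs], dtype=float
    ).reshape(-1, 2)


@dataclass
class MatchResult:
    """One-to-one matching between two point sets (nm coordinates)."""

    pairs: list[tuple[int, int, float]]  # (index_a, index_b, distance_nm)
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def matched_fraction_of_b(self) -> float:
        n_b = len(self.pairs) + len(self.unmatched_b)
        if n_b == 0:
            return float("nan")
        return len(self.pairs) / n_b

    @property
    def total_distance_nm(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


def colocalize(puncta_a, puncta_b, match_radius_nm: float = 300.0) -> MatchResult:
    """Optimally match channel-B puncta to channel-A puncta within a radius."""
    xy_a = _as_xy_nm(puncta_a)
    xy_b = _as_xy_nm(puncta_b)
    n_a, n_b = len(xy_a), len(xy_b)
    if n_a == 0 or n_b == 0:
        return MatchResult(
            pairs=[], unmatched_a=list(range(n_a)), unmatched_b=list(range(n_b))
        )
    dist = cdist(xy_a, xy_b)
    cost = np.where(dist <= match_radius_nm, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= match_radius_nm
    ]
    matched_a = {i for i, _, _ in pairs}
    matched_b = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_a=[i for i in range(n_a) if i not in matched_a],
        unmatched_b=[j for j in range(n_b) if j not in matched_b],
    )


@dataclass
class AssociationResult:
    """Per-punctum FREE/BOUND labels plus per-Golgi ring summaries."""

    golgi_id: np.ndarray  # int per punctum, -1 = FREE
    distance_nm: np.ndarray  # distance to the assigned Golgi (nan if FREE)
    n_bound: int
    n_free: int
    bound_ci: ProportionEstimate | None
    rings: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def free_to_bound_ratio(self) -> float:
        if self.n_bound == 0:
            return float("inf") if self.n_free else float("nan")
        return self.n_free / self.n_bound

    @property
    def states(self) -> list[str]:
        return ["BOUND" if g >= 0 else "FREE" for g in self.golgi_id]


def classify_association(
    puncta,
    golgi: list[GolgiObject],
    assoc_radius_nm: float = 1000.0,
    pixel_size_nm: float | None = None,
    min_ring_members: int = 3,
) -> AssociationResult:
    """Label each punctum BOUND to its nearest Golgi within the radius,
    else FREE. Ties (within 1 nm) go to the lower Golgi id."""
    xy_p = _as_xy_nm(puncta)
    n = len(xy_p)
    gid = np.full(n, -1, dtype=int)
    dist_out = np.full(n, np.nan)

    golgi_ids = np.array(
        [g.id if g.id is not None else k for k, g in enumerate(golgi)], dtype=int
    )
    if n and len(golgi):
        xy_g = _as_xy_nm(golgi)
        # sort Golgi by id so argmin ties resolve to the lower id
        order = np.argsort(golgi_ids, kind="stable")
        xy_g, golgi_ids_sorted = xy_g[order], golgi_ids[order]
        dist = cdist(xy_p, xy_g)
        dist_round = np.round(dist, 0)  # 1-nm tie tolerance
        best = np.argmin(dist_round, axis=1)
        best_d = dist[np.arange(n), best]
        within = best_d <= assoc_radius_nm
        gid[within] = golgi_ids_sorted[best[within]]
        dist_out[within] = best_d[within]

    n_bound = int(np.sum(gid >= 0))
    n_free = n - n_bound
    ci = proportion_ci(n_bound, n) if n else None

    rows = []
    for g in golgi:
        g_id = g.id if g.id is not None else 0
        members = np.where(gid == g_id)[0]
        diam = ring_diameter(g, [puncta[i] for i in members]) if len(members) else float("nan")
        rows.append(
            {
                "golgi_id": g_id,
                "n_members": int(len(members)),
                "ring_diameter_nm": diam if len(members) >= min_ring_members else float("nan"),
            }
        )
    rings = pd.DataFrame(rows, columns=["golgi_id", "n_members", "ring_diameter_nm"])
    return AssociationResult(
        golgi_id=gid,
        distance_nm=dist_out,
        n_bound=n_bound,
        n_free=n_free,
        bound_ci=ci,
        rings=rings,
    )


def ring_diameter(golgi, member_puncta) -> float:
    """2x the mean member-to-Golgi-centroid distance; NaN below 3 members."""
    members = _as_xy_nm(member_puncta)
    if len(members) < 3:
        return float("nan")
    center = _as_xy_nm([golgi])[0] if not isinstance(golgi, np.ndarray) else np.asarray(golgi, float)
    dists = np.linalg.norm(members - center, axis=1)
    return float(2.0 * dists.mean())


def association_table(
    puncta: list[Punctum], result: AssociationResult, frame: int
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": frame,
            "punctum_id": np.arange(len(puncta)),
            "state": result.states,
            "golgi_id": result.golgi_id,
            "distance_nm": result.distance_nm,
        }
    )


def default_association_params() -> AssociationParams:
    return AssociationParams()
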