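"""Summary statistics: binomial proportion intervals, replicate pooling,
mean +/- SEM."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, norm

__all__ = ["ProportionEstimate", "proportion_ci", "pool_replicates", "mean_sem"]


@dataclass
class ProportionEstimate:
    k: int
    n: int
    point: float
    low: float
    high: float
    level: float = 0.95
    method: str = "wilson"


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> ProportionEstimate:
    """Confidence interval for a binomial proportion.

    Wilson score by default (well-behaved at proportions near 0 and 1);
    Clopper-Pearson available as ``method='clopper-pearson'``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    if method == "wilson":
        z = norm.ppf(0.5 + level / 2.0)
        z2 = z * z
        denom = 1.0 + z2 / n
        center = (p + z2 / (2 * n)) / denom
        half = (z / denom) * np.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
        low, high = center - half, center + half
        # analytically exact at the boundaries; avoid float round-off
        if k == 0:
            low = 0.0
        if k == n:
            high = 1.0
    elif method == "clopper-pearson":
        alpha = 1.0 - level
        low = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    else:
        raise ValueError(f"unknown method {method!r}")
    low = float(np.clip(low, 0.0, 1.0))
    high = float(np.clip(high, 0.0, 1.0))
    return ProportionEstimate(k=int(k), n=int(n), point=p, low=low, high=high,
                              level=level, method=method)


def pool_replicates(
    counts: Iterable[tuple[int, int]],
    level: float = 0.95,
    method: str = "wilson",
) -> tuple[ProportionEstimate, pd.DataFrame]:
    """Sum (k, n) across replicate movies before interval computation.

    Returns the pooled estimate plus a per-replicate table kept for
    dispersion reporting.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("need at least one replicate")
    table = pd.DataFrame(counts, columns=["k", "n"])
    table["proportion"] = table["k"] / table["n"].where(table["n"] > 0)
    pooled = proportion_ci(
        int(table["k"].sum()), int(table["n"].sum()), level=level, method=method
    )
    return pooled, table


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error of the mean (ddof=1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
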