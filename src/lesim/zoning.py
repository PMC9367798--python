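"""Ecological zoning: natural-breaks classification of the adjusted LESI.

The study area is cut into four security levels by Fisher-Jenks natural
breaks on the adjusted index: urban development zone (UDZ, lowest
security), ecological optimization zone (EOZ), ecological buffer zone
(EBZ), and ecological core zone (ECZ, highest). Classification operates
on the adjusted index; the reported per-zone thresholds are
back-translated to raw-index units as the minimum raw value observed in
each class.

Boundary convention: the top class is open below (ECZ strictly above the
top break); the lower classes are closed on their upper boundary
(``b_{k-1} < v <= b_k``); values below the bottom of the data clamp to UDZ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = ["ZONE_NAMES", "EcoZoning", "jenks_breaks", "classify_zones", "zone_shares"]

#: Zone codes in ascending security order.
ZONE_NAMES = {1: "UDZ", 2: "EOZ", 3: "EBZ", 4: "ECZ"}


def jenks_breaks(values, k: int) -> np.ndarray:
    """Optimal 1-D natural breaks (Fisher-Jenks) into k classes.

    Returns the k-1 breakpoints, each the maximum value of a lower class,
    minimizing the total within-class sum of squared deviations. Exact
    O(k n^2) dynamic programming over the sorted values; classes are
    never empty.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValueError("fewer distinct values than classes")

    # prefix sums for O(1) within-class SSD of x[i:j]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    # cost[c][j]: best cost partitioning x[:j] into c classes; inner
    # minimization over the last cut i is vectorized per (c, j)
    cost = np.full((k + 1, n + 1), np.inf)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            m = j - i
            total = s1[j] - s1[i]
            ssd = (s2[j] - s2[i]) - total * total / m
            cand = cost[c - 1, c - 1 : j] + ssd
            arg = int(np.argmin(cand))
            cost[c, j] = cand[arg]
            cut[c, j] = c - 1 + arg
    # backtrack class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = cut[c, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop leading 0; k-1 cut indices
    return np.array([x[b - 1] for b in bounds])


@dataclass
class EcoZoning:
    """Zone assignment plus per-zone accounting.

    ``zones`` holds codes 1..4 (UDZ..ECZ) per unit — an integer
    :class:`RasterGrid` when classifying a raster, an ndarray otherwise.
    Areas are km**2; shares are percent of the zoned total; thresholds
    are the per-zone minimum *raw* index when raw values are supplied.
    """

    zones: RasterGrid | np.ndarray
    breaks: np.ndarray
    areas_km2: dict[str, float]
    shares_pct: dict[str, float]
    mean_raw_lesi: dict[str, float]
    raw_thresholds: dict[str, float]

    def report(self) -> pd.DataFrame:
        rows = []
        for code in sorted(ZONE_NAMES, reverse=True):
            z = ZONE_NAMES[code]
            rows.append(
                {
                    "zone": z,
                    "area_km2": self.areas_km2.get(z, 0.0),
                    "share_pct": self.shares_pct.get(z, 0.0),
                    "mean_raw_lesi": self.mean_raw_lesi.get(z, np.nan),
                    "raw_threshold": self.raw_thresholds.get(z, np.nan),
                }
            )
        return pd.DataFrame(rows)


def classify_zones(lesi, breaks, raw=None, cell_area_km2: float = 1.0) -> EcoZoning:
    """Assign four ecological zones from three strictly increasing breaks.

    ``lesi`` is the adjusted index as a :class:`RasterGrid` or array;
    ``raw`` optionally carries the raw (pre-adjustment) index on the same
    layout for threshold/mean reporting. Monotone: a higher index never
    lands in a lower-security zone; ECZ requires a value strictly above
    the top break.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.size != 3 or not np.all(np.diff(breaks) > 0):
        raise ValueError("need 3 strictly increasing breakpoints")

    if isinstance(lesi, RasterGrid):
        vals, mask = lesi.values.astype(float), lesi.mask
        cell_area_km2 = lesi.cell_area_km2
    else:
        vals = np.asarray(lesi, dtype=float)
        mask = np.isfinite(vals)

    # v <= b1 -> UDZ(1); b1 < v <= b2 -> EOZ(2); b2 < v <= b3 -> EBZ(3); v > b3 -> ECZ(4)
    codes = 1 + np.searchsorted(breaks, vals, side="left").astype(np.int32)
    codes = np.where(mask, codes, 0)

    raw_vals = None
    if raw is not None:
        raw_vals = raw.values.astype(float) if isinstance(raw, RasterGrid) else np.asarray(raw, dtype=float)

    areas, shares, means, thresholds = {}, {}, {}, {}
    total = int(mask.sum())
    if total == 0:
        raise ValueError("no data cells to classify")
    for code, name in ZONE_NAMES.items():
        sel = (codes == code) & mask
        n = int(sel.sum())
        areas[name] = n * cell_area_km2
        if raw_vals is not None and n:
            means[name] = float(raw_vals[sel].mean())
            thresholds[name] = float(raw_vals[sel].min())
    shares = zone_shares(areas)

    if isinstance(lesi, RasterGrid):
        zgrid = lesi.with_values(codes)
        zgrid.nodata = 0.0
        zones = zgrid
    else:
        zones = codes
    return EcoZoning(zones, breaks, areas, shares, means, thresholds)


def zone_shares(areas: dict[str, float]) -> dict[str, float]:
    """Percent share of each zone in the zoned total."""
    if any(a < 0 for a in areas.values()):
        raise ValueError("negative area")
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("zero total area")
    return {z: 100.0 * a / total for z, a in areas.items()}
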