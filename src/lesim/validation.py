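"""Map agreement and change accounting.

Calibration compares a simulated map with the observed map over the full
non-nodata census: a 6x6 confusion matrix yields the overall accuracy
p0 (observed agreement) and Cohen's kappa = (p0 - pe)/(1 - pe), where pe
is the agreement expected by chance from the marginals. Change tables and
zone-by-class tables reproduce the standard area accounting: per-class
area at two dates, difference (km**2) and percentage change, and the
distribution of each class across ecological zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import LandUseMap
from .zoning import ZONE_NAMES, EcoZoning

__all__ = ["AgreementStats", "crosstab", "kappa", "change_table", "zone_landuse_table"]


@dataclass
class AgreementStats:
    """Confusion matrix with overall accuracy and chance-corrected kappa."""

    matrix: pd.DataFrame
    p0: float
    pe: float
    kappa: float

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def crosstab(a: LandUseMap, b: LandUseMap) -> pd.DataFrame:
    """Confusion matrix of co-occurring class pairs (rows: a, cols: b).

    Only cells that carry data in both maps are counted.
    """
    if not a.grid.aligned_with(b.grid):
        raise ValueError("maps are not aligned")
    if a.legend != b.legend:
        raise ValueError("legend mismatch")
    codes = a.codes
    k = len(codes)
    both = a.grid.mask & b.grid.mask
    ia = np.searchsorted(codes, a.grid.values[both])
    ib = np.searchsorted(codes, b.grid.values[both])
    counts = np.bincount(ia * k + ib, minlength=k * k).reshape(k, k)
    return pd.DataFrame(counts, index=codes, columns=codes)


def kappa(matrix: pd.DataFrame) -> AgreementStats:
    """Cohen's kappa from a confusion matrix.

    p0 = trace/total, pe = sum(row_c * col_c)/total**2,
    kappa = (p0 - pe)/(1 - pe).
    """
    m = matrix.to_numpy(dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(m) / total
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if pe >= 1:
        raise ValueError("degenerate single-class maps: pe = 1")
    return AgreementStats(matrix, float(p0), pe, (p0 - pe) / (1 - pe))


def change_table(
    t0, t1_by_scenario: dict[str, object], class_names: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-class area change between a base date and scenario outcomes.

    Inputs are :class:`LandUseMap` objects (areas from cell counts) or
    mappings class -> area km**2 (printed areas pass through unchanged).
    Columns: class, area_t0, area_<scn>, diff_<scn> (km**2), and
    pct_<scn> = 100 x diff / area_t0.
    """

    def areas_of(obj) -> dict:
        if isinstance(obj, LandUseMap):
            return obj.class_areas_km2()
        return dict(obj)

    a0 = areas_of(t0)
    rows = []
    for cls in a0:
        name = (class_names or {}).get(cls, cls)
        row = {"class": name, "area_t0": a0[cls]}
        for scn, t1 in t1_by_scenario.items():
            a1 = areas_of(t1)
            diff = a1[cls] - a0[cls]
            row[f"area_{scn}"] = a1[cls]
            row[f"diff_{scn}"] = diff
            if a0[cls] == 0:
                raise ValueError(f"zero base area for class {cls}")
            row[f"pct_{scn}"] = 100.0 * diff / a0[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def zone_landuse_table(landuse: LandUseMap, zoning: EcoZoning) -> pd.DataFrame:
    """Area and row-proportion of each land class across ecological zones.

    Rows: land class. Columns: area_<zone> (km**2) and prop_<zone> (% of
    the class total); proportions in each row sum to 100.
    """
    zones = zoning.zones
    zvals = zones.values if hasattr(zones, "values") else np.asarray(zones)
    if zvals.shape != landuse.grid.shape:
        raise ValueError("zone raster misaligned with land-use map")
    cell = landuse.grid.cell_area_km2
    mask = landuse.grid.mask & (zvals > 0)
    rows = []
    for cls in landuse.codes:
        sel = (landuse.grid.values == cls) & mask
        total = sel.sum() * cell
        row = {"class": cls, "total_km2": total}
        for code, zname in ZONE_NAMES.items():
            a = ((zvals == code) & sel).sum() * cell
            row[f"area_{zname}"] = a
            row[f"prop_{zname}"] = 100.0 * a / total if total > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
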