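"""Per-class suitability atlases: restrictions x weighted linear combination.

A class's suitability image is the product of a Boolean restriction mask
(cells where conversion *to* that class is admissible at all) and a convex
combination of fuzzy-standardized constraint factors. Restrictions exclude
cells already of the class, permanently protected categories (basic
farmland, water, urban land at the base date), and — for construction
under the ecological-protection scenario — the ecological core zone.
Protected categories are additionally *frozen* in the automaton (they
never change class in either direction); see :mod:`lesim.camarkov`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RasterGrid, LandUseMap, check_aligned, minmax_rescale

__all__ = ["SuitabilityAtlas", "restriction_mask", "fuzzy_factor", "wlc_combine", "build_atlas"]

SCENARIOS = {"ND", "EP"}


@dataclass
class SuitabilityAtlas:
    """One [0, 1] suitability raster per simulated class, with provenance."""

    rasters: dict[int, RasterGrid]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not check_aligned(list(self.rasters.values())):
            raise ValueError("atlas rasters are not aligned")
        for code, g in self.rasters.items():
            v = g.values[g.mask]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError(f"suitability for class {code} outside [0, 1]")

    def __getitem__(self, code: int) -> RasterGrid:
        return self.rasters[code]


def restriction_mask(
    land_class: int,
    base: LandUseMap,
    protected: list[np.ndarray] | None = None,
    scenario: str = "ND",
    eco_core: np.ndarray | None = None,
) -> RasterGrid:
    """Cells available for conversion *to* ``land_class`` (True = available).

    Unavailable: cells already of the class; protected masks (permanent
    basic farmland, water areas, urban land at the base date); and, for
    construction under the EP scenario, the ecological core zone. The
    natural-development scenario sets no ecological restriction.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {sorted(SCENARIOS)}")
    available = base.grid.mask.copy()
    available &= base.grid.values != land_class
    for mask in protected or []:
        m = mask.values.astype(bool) if isinstance(mask, RasterGrid) else np.asarray(mask, bool)
        if m.shape != available.shape:
            raise ValueError("protected mask misaligned")
        available &= ~m
    is_construction = base.legend.get(land_class) == "construction"
    if scenario == "EP" and is_construction:
        if eco_core is None:
            raise ValueError("EP scenario needs the ecological core mask for construction")
        core = eco_core.values.astype(bool) if isinstance(eco_core, RasterGrid) else np.asarray(eco_core, bool)
        if core.shape != available.shape:
            raise ValueError("eco-core mask misaligned")
        available &= ~core
    out = base.grid.with_values(available)
    out.nodata = -1.0
    return out


def fuzzy_factor(raster: RasterGrid, sign: str) -> RasterGrid:
    """Linear min-max membership of a constraint factor.

    ``'+'`` (positive association) rises with the factor; ``'-'`` falls.
    """
    if sign not in {"+", "-"}:
        raise ValueError("sign must be '+' or '-'")
    return minmax_rescale(raster, "increasing" if sign == "+" else "decreasing")


def wlc_combine(
    factors: list[tuple[RasterGrid, float]],
    restriction: RasterGrid,
) -> RasterGrid:
    """Weighted linear combination masked by the restriction.

    S = restriction x sum(w_i f_i); weights must be non-negative and sum
    to 1 within 1e-6, so S is a convex combination of memberships on
    unrestricted cells and exactly 0 on restricted ones.
    """
    if not factors:
        raise ValueError("no factors")
    weights = np.array([w for _, w in factors], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be >= 0 and sum to 1")
    grids = [g for g, _ in factors] + [restriction]
    if not check_aligned(grids):
        raise ValueError("factor rasters misaligned")
    avail = restriction.values.astype(bool)
    combo = np.zeros(restriction.shape, dtype=float)
    for (g, w) in factors:
        vals = np.where(g.mask, g.values.astype(float), 0.0)
        combo += w * vals
    combo = np.clip(combo, 0.0, 1.0)
    combo[~avail] = 0.0
    out = restriction.with_values(combo)
    out.nodata = -9999.0
    return out


def build_atlas(
    base: LandUseMap,
    stack,
    class_weights: dict[int, dict[str, tuple[float, str]]],
    scenario: str = "ND",
    eco_core=None,
    protected=None,
) -> SuitabilityAtlas:
    """Assemble the full atlas from a driver stack and per-class weights.

    ``class_weights[code]`` maps factor name -> (weight, sign). Fuzzy
    memberships are computed once per (factor, sign) pair and combined per
    class under that class's restriction mask.
    """
    memberships: dict[tuple[str, str], RasterGrid] = {}
    rasters: dict[int, RasterGrid] = {}
    for code, wmap in class_weights.items():
        fs = []
        for name, (w, sign) in wmap.items():
            key = (name, sign)
            if key not in memberships:
                memberships[key] = fuzzy_factor(stack.layers[name], sign)
            fs.append((memberships[key], w))
        restr = restriction_mask(code, base, protected=protected, scenario=scenario, eco_core=eco_core)
        rasters[code] = wlc_combine(fs, restr)
    provenance = {
        "scenario": scenario,
        "weights": {
            str(code): {n: [w, s] for n, (w, s) in wmap.items()}
            for code, wmap in class_weights.items()
        },
    }
    return SuitabilityAtlas(rasters, provenance)
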