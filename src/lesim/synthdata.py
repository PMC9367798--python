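"""Seeded synthetic landscapes, driver stacks, and indicator tables.

The generator emulates the statistical structure the pipeline assumes of
its real inputs: co-registered categorical rasters with spatially
autocorrelated class patches, a second date derived by boundary-biased
transitions at declared per-decade intensities, monotone driver surfaces
(population decaying away from towns, smooth elevation with slope as its
gradient), and per-unit indicator tables with mixed positive/negative
attributes. Every draw flows from a single spec seed through named
substreams (landscape, drivers, indicators), so regenerating one
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .camarkov import largest_remainder, neighborhood_factor
from .drivers import DriverStack
from .grids import DEFAULT_LEGEND, LandUseMap, RasterGrid, euclidean_distance
from .les_cpm import DEFAULT_PSR_ATTRIBUTES, IndicatorTable

__all__ = ["SynthSpec", "synth_landscape", "synth_drivers", "synth_indicators"]

#: Default class budget: farmland-, woodland-, construction-dominated
#: landscape with minor grassland / water / unused, mirroring a
#: peri-urban study area.
DEFAULT_BUDGET = {1: 0.28, 2: 0.40, 3: 0.02, 4: 0.08, 5: 0.21, 6: 0.01}

#: Default per-decade transition intensities (from -> to): construction
#: expands into farmland and woodland; minor reshuffling elsewhere.
DEFAULT_DRIFT = {
    (1, 5): 0.08,
    (2, 5): 0.03,
    (2, 1): 0.02,
    (1, 2): 0.01,
    (3, 5): 0.05,
    (4, 5): 0.01,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic world. ``seed`` is mandatory."""

    rows: int = 200
    cols: int = 200
    cell_size: float = 30.0
    class_budget: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BUDGET))
    patch_radius: float = 8.0
    drift: dict[tuple[int, int], float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    driver_noise_sd: float = 0.15
    n_towns: int = 4
    unit_cells: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.class_budget.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        n = self.rows * self.cols
        if any(p * n < 1 for p in self.class_budget.values() if p > 0):
            raise ValueError("budget infeasible on this grid size")

    def rng(self, stream: str) -> np.random.Generator:
        offsets = {"landscape": 1, "drivers": 2, "indicators": 3}
        return np.random.default_rng([self.seed, offsets[stream]])


def _grow_patches(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Budget-constrained nearest-nucleus growth: contiguous class patches."""
    rows, cols, n = spec.rows, spec.cols, spec.rows * spec.cols
    codes = sorted(spec.class_budget)
    budgets = largest_remainder(
        np.array([spec.class_budget[c] * n for c in codes]), total=n
    )
    area_per_patch = np.pi * spec.patch_radius**2
    dist = {}
    for c, b in zip(codes, budgets):
        k = max(1, int(round(b / area_per_patch)))
        nuclei = np.zeros((rows, cols), dtype=bool)
        pts = rng.integers(0, [rows, cols], size=(k, 2))
        nuclei[pts[:, 0], pts[:, 1]] = True
        dist[c] = ndimage.distance_transform_edt(~nuclei)
    # assign cells in order of distance to their nearest nucleus; a full
    # class passes the cell to the next-nearest class with budget left
    D = np.stack([dist[c].ravel() for c in codes])  # (k, n)
    nearest = D.min(axis=0)
    order = np.argsort(nearest, kind="stable")
    pref = np.argsort(D, axis=0, kind="stable")  # class preference per cell
    remaining = {i: int(b) for i, b in enumerate(budgets)}
    out = np.empty(n, dtype=np.int32)
    for cell in order:
        for ci in pref[:, cell]:
            if remaining[ci] > 0:
                out[cell] = codes[ci]
                remaining[ci] -= 1
                break
    return out.reshape(rows, cols)


def synth_landscape(spec: SynthSpec) -> tuple[LandUseMap, LandUseMap]:
    """Generate an aligned (t0, t1) land-use map pair.

    t0 grows contiguous patches from random nuclei until class budgets
    are met; t1 applies the drift intensities preferentially at class
    boundaries, so change is spatially autocorrelated and
    ``transitions(t0, t1)[u, v]`` recovers ``drift[(u, v)]`` up to
    integer rounding.
    """
    rng = spec.rng("landscape")
    values = _grow_patches(spec, rng)
    grid = RasterGrid(values, cell_size=spec.cell_size)
    legend = {c: DEFAULT_LEGEND[c] for c in sorted(spec.class_budget)}
    t0 = LandUseMap(grid, legend)

    v1 = values.copy()
    for (u, v), rate in sorted(spec.drift.items()):
        if rate <= 0:
            continue
        src = values == u
        n_flip = int(round(rate * src.sum()))
        if n_flip == 0:
            continue
        # prefer cells of u adjacent to v: boundary-biased change
        h = neighborhood_factor(
            LandUseMap(grid.with_values(v1), legend), v, window=5
        ).values
        cand = src & (v1 == u)  # still unconverted
        rr, cc = np.nonzero(cand)
        score = h[rr, cc] + rng.uniform(0, 1e-6, size=rr.size)
        take = np.argsort(-score, kind="stable")[:n_flip]
        v1[rr[take], cc[take]] = v
    t1 = LandUseMap(grid.with_values(v1), legend)
    return t0, t1


def _random_path(rng, rows, cols) -> np.ndarray:
    """A meandering one-cell-wide line spanning the grid top to bottom."""
    mask = np.zeros((rows, cols), dtype=bool)
    pos = int(rng.integers(cols // 4, 3 * cols // 4))
    for r in range(rows):
        pos = int(np.clip(pos + rng.integers(-1, 2), 0, cols - 1))
        mask[r, pos] = True
    return mask


def synth_drivers(spec: SynthSpec, landscape: LandUseMap) -> DriverStack:
    """Driver stack consistent with the landscape.

    Distance factors (DR, DRS, DH, DT) come from synthesized river, rural
    settlement, highway, and town masks; POP decays exponentially with
    distance to town plus multiplicative noise; ELE is a smooth random
    field and SLO its gradient magnitude.
    """
    rng = spec.rng("drivers")
    rows, cols = landscape.grid.shape
    cell = landscape.grid.cell_size

    river = _random_path(rng, rows, cols)
    highway = _random_path(rng, cols, rows).T  # spans left to right

    towns = np.zeros((rows, cols), dtype=bool)
    constr = landscape.class_mask(5)
    if constr.any():
        rr, cc = np.nonzero(constr)
        pick = rng.choice(rr.size, size=min(spec.n_towns, rr.size), replace=False)
        towns[rr[pick], cc[pick]] = True
    else:
        pts = rng.integers(0, [rows, cols], size=(spec.n_towns, 2))
        towns[pts[:, 0], pts[:, 1]] = True

    rural = np.zeros((rows, cols), dtype=bool)
    pts = rng.integers(0, [rows, cols], size=(max(6, spec.n_towns * 3), 2))
    rural[pts[:, 0], pts[:, 1]] = True

    def dist(mask: np.ndarray) -> RasterGrid:
        return euclidean_distance(landscape.grid.with_values(mask))

    dr, drs, dh, dt = dist(river), dist(rural), dist(highway), dist(towns)

    decay = max(rows, cols) * cell / 5.0
    noise = np.exp(rng.normal(0.0, spec.driver_noise_sd, size=(rows, cols)))
    pop = 5000.0 * np.exp(-dt.values / decay) * noise

    ele = ndimage.gaussian_filter(rng.normal(size=(rows, cols)), sigma=rows / 8)
    ele = (ele - ele.min()) / (ele.max() - ele.min() + 1e-12) * 500.0
    gy, gx = np.gradient(ele, cell)
    slo = np.degrees(np.arctan(np.hypot(gx, gy)))

    base = landscape.grid
    layers = {
        "POP": base.with_values(pop),
        "DR": dr,
        "DRS": drs,
        "DH": dh,
        "DT": dt,
        "SLO": base.with_values(slo),
        "ELE": base.with_values(ele),
    }
    return DriverStack(layers)


#: Default per-indicator (mean, sd) on arbitrary measurement scales; the
#: attribute set matches the standard PSR battery.
def _default_indicator_model() -> dict[str, tuple[float, float, str]]:
    model = {}
    for i, (name, attr) in enumerate(DEFAULT_PSR_ATTRIBUTES.items(), start=1):
        mean = 10.0 * i
        model[name] = (mean, 0.3 * mean, attr)
    return model


def synth_indicators(
    spec: SynthSpec,
    landscape: LandUseMap | None = None,
    model: dict[str, tuple[float, float, str]] | None = None,
) -> IndicatorTable:
    """Per-unit indicator table over square blocks of the grid.

    Units are non-overlapping ``unit_cells x unit_cells`` blocks. Values
    are normal draws from the per-indicator model. In coupled mode
    (``landscape`` given) the land-cover-share indicators are replaced by
    the actual block shares: D5 (construction %), D7 (woodland %), and
    D8 (water %), so end-to-end runs see consistent maps and tables.
    """
    rng = spec.rng("indicators")
    model = model or _default_indicator_model()
    nr, nc = spec.rows // spec.unit_cells, spec.cols // spec.unit_cells
    if nr * nc < 2:
        raise ValueError("need at least 2 units")
    unit_ids = [f"u{r}_{c}" for r in range(nr) for c in range(nc)]
    data = {
        name: rng.normal(mean, sd, size=len(unit_ids))
        for name, (mean, sd, _) in model.items()
    }
    attributes = {name: attr for name, (_, _, attr) in model.items()}
    table = pd.DataFrame(data, index=pd.Index(unit_ids, name="unit_id"))

    if landscape is not None:
        u = spec.unit_cells
        shares = {"D5": 5, "D7": 2, "D8": 4}
        for ind, code in shares.items():
            if ind not in table.columns:
                continue
            vals = []
            m = landscape.grid.values
            for r in range(nr):
                for c in range(nc):
                    block = m[r * u : (r + 1) * u, c * u : (c + 1) * u]
                    vals.append(100.0 * np.mean(block == code))
            table[ind] = vals
    return IndicatorTable(table, attributes)
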