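"""Coupled Markov-chain / cellular-automaton land-use allocation.

The Markov stage estimates a row-stochastic transition matrix from two
dated maps and projects per-class cell demands for the target date. The
CA stage then allocates the projected change spatially over a fixed
number of cycles: a cell's next state depends on its current state, the
class composition of its neighborhood (edge-truncated square window,
default 5x5), and the suitability atlas Q.

Allocation is greedy and deterministic: candidate cells for gaining class
v are scored Q_v x (eps + h_v) with eps = 0.01 (the floor keeps isolated
high-suitability cells reachable), gaining classes are processed in
descending remaining demand, each cell changes at most once per cycle,
frozen and restricted cells never change, and ties break by (row, col)
order. Demand is spread over cycles on a linear schedule (cumulative t/T
of the total change, largest-remainder rounded), so identical inputs give
a bit-identical output map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import RasterGrid, LandUseMap
from .suitability import SuitabilityAtlas

__all__ = [
    "TransitionMatrix",
    "CAConfig",
    "CAState",
    "transition_matrix",
    "project_demand",
    "largest_remainder",
    "neighborhood_factor",
    "allocate_cycle",
    "simulate",
]

EPSILON = 0.01  # neighborhood floor in the allocation score


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition probabilities plus base-date counts."""

    codes: list[int]
    P: np.ndarray
    base_counts: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.base_counts = np.asarray(self.base_counts)
        k = len(self.codes)
        if self.P.shape != (k, k):
            raise ValueError("P shape disagrees with codes")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1 within 1e-9")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.codes, columns=self.codes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, base_counts) -> "TransitionMatrix":
        codes = [int(c) for c in frame.index]
        return cls(codes, frame.to_numpy(dtype=float), np.asarray(base_counts))


@dataclass
class CAConfig:
    """Automaton settings: cycles, window, scenario, frozen cells, seed."""

    cycles: int = 10
    filter_size: int = 5
    scenario: str = "ND"
    frozen: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError("filter side must be odd and >= 3")


@dataclass
class CAState:
    """Mutable automaton state between cycles."""

    landuse: LandUseMap
    remaining: dict[tuple[int, int], int]
    allocated: dict[tuple[int, int], int] = field(default_factory=dict)
    cycle: int = 0


def transition_matrix(from_map: LandUseMap, to_map: LandUseMap) -> TransitionMatrix:
    """Estimate P[u][v] = (cells u at t0 that are v at t1) / (cells u at t0).

    Classes absent at the base date carry identity rows. Only cells that
    are non-nodata in both maps are counted.
    """
    if not from_map.grid.aligned_with(to_map.grid):
        raise ValueError("maps are not aligned")
    if from_map.legend != to_map.legend:
        raise ValueError("legend mismatch")
    codes = from_map.codes
    k = len(codes)
    idx = {c: i for i, c in enumerate(codes)}
    both = from_map.grid.mask & to_map.grid.mask
    a = from_map.grid.values[both]
    b = to_map.grid.values[both]
    counts = np.zeros((k, k), dtype=np.int64)
    flat = np.array([idx[c] for c in codes])[
        np.searchsorted(codes, a)
    ] * k + np.array([idx[c] for c in codes])[np.searchsorted(codes, b)]
    binc = np.bincount(flat, minlength=k * k)
    counts = binc.reshape(k, k)
    base = counts.sum(axis=1)
    P = np.eye(k)
    present = base > 0
    P[present] = counts[present] / base[present, None]
    return TransitionMatrix(codes, P, base)


def largest_remainder(quotas: np.ndarray, total: int | None = None) -> np.ndarray:
    """Round non-negative quotas to integers conserving the (rounded) total."""
    quotas = np.asarray(quotas, dtype=float)
    if total is None:
        total = int(round(quotas.sum()))
    floors = np.floor(quotas).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        remainders = quotas - floors
        # largest remainders first; ties by position for determinism
        order = np.lexsort((np.arange(quotas.size), -remainders))
        floors[order[:short]] += 1
    elif short < 0:
        order = np.lexsort((np.arange(quotas.size), quotas - floors))
        take = [i for i in order if floors[i] > 0][: -short]
        floors[take] -= 1
    return floors


def project_demand(P: TransitionMatrix, base_counts=None) -> np.ndarray:
    """Target cells per class: base_counts . P, largest-remainder rounded.

    Each matrix row is integerized by largest remainder (outflow per class
    sums to its base count), and targets are the column sums, so the total
    cell count is conserved exactly and the targets agree cell-for-cell
    with the per-pair demands the allocator satisfies.
    """
    base = np.asarray(P.base_counts if base_counts is None else base_counts)
    rows = np.stack(
        [largest_remainder(base[i] * P.P[i], total=int(base[i])) for i in range(len(base))]
    )
    return rows.sum(axis=0)


def pair_demands(P: TransitionMatrix, base_counts=None) -> dict[tuple[int, int], int]:
    """Projected change per ordered class pair (u -> v), u != v.

    Each matrix row is integerized by largest remainder so per-class
    outflow sums to the class's base count.
    """
    base = np.asarray(P.base_counts if base_counts is None else base_counts)
    out: dict[tuple[int, int], int] = {}
    for i, u in enumerate(P.codes):
        row = largest_remainder(base[i] * P.P[i], total=int(base[i]))
        for j, v in enumerate(P.codes):
            if i != j and row[j] > 0:
                out[(u, v)] = int(row[j])
    return out


def neighborhood_factor(
    landuse: LandUseMap, land_class: int, window: int = 5
) -> RasterGrid:
    """Fraction of the (edge-truncated) window currently in the class."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd")
    binary = ((landuse.grid.values == land_class) & landuse.grid.mask).astype(float)
    kernel = np.ones((window, window))
    hits = ndimage.correlate(binary, kernel, mode="constant", cval=0.0)
    denom = ndimage.correlate(np.ones_like(binary), kernel, mode="constant", cval=0.0)
    out = landuse.grid.with_values(hits / denom)
    out.nodata = -9999.0
    return out


def _cycle_quota(
    totals: dict[tuple[int, int], int],
    allocated: dict[tuple[int, int], int],
    t: int,
    T: int,
) -> dict[tuple[int, int], int]:
    """This cycle's per-pair quota from the cumulative linear schedule."""
    pairs = sorted(totals)
    target_vec = largest_remainder(
        np.array([totals[p] * t / T for p in pairs], dtype=float)
    )
    return {
        p: max(0, int(target_vec[i]) - allocated.get(p, 0))
        for i, p in enumerate(pairs)
    }


def allocate_cycle(
    state: CAState,
    atlas: SuitabilityAtlas,
    quota: dict[tuple[int, int], int],
    config: CAConfig,
    log: list | None = None,
) -> CAState:
    """Run one automaton cycle, converting up to ``quota`` cells per pair.

    Neighborhood factors reflect the state at the start of the cycle; a
    cell changes at most once per cycle; frozen cells and cells with zero
    suitability (restricted) never change. If a pair's eligible cells run
    out, the shortfall is logged and carried to later cycles.
    """
    lu = state.landuse
    values = lu.grid.values.copy()
    mask = lu.grid.mask
    frozen = config.frozen if config.frozen is not None else np.zeros(lu.grid.shape, bool)
    locked = np.zeros(lu.grid.shape, dtype=bool)

    gaining = sorted(
        {v for (_, v), q in quota.items() if q > 0},
        key=lambda v: (-sum(q for (u, vv), q in quota.items() if vv == v), v),
    )
    h = {
        v: neighborhood_factor(
            LandUseMap(lu.grid.with_values(values), lu.legend), v, config.filter_size
        ).values
        for v in gaining
    }

    allocated = dict(state.allocated)
    remaining = dict(state.remaining)
    for v in gaining:
        Q = atlas[v].values
        score = Q * (EPSILON + h[v])
        sources = sorted(
            [u for (u, vv), q in quota.items() if vv == v and q > 0],
            key=lambda u: (-quota[(u, v)], u),
        )
        for u in sources:
            want = quota[(u, v)]
            eligible = (values == u) & mask & ~frozen & ~locked & (Q > 0)
            rr, cc = np.nonzero(eligible)
            if rr.size:
                s = score[rr, cc]
                order = np.lexsort((cc, rr, -s))
                take = order[:want]
                values[rr[take], cc[take]] = v
                locked[rr[take], cc[take]] = True
                got = len(take)
            else:
                got = 0
            allocated[(u, v)] = allocated.get((u, v), 0) + got
            remaining[(u, v)] = remaining.get((u, v), 0) - got
            if log is not None and got < want:
                log.append(
                    {"cycle": state.cycle + 1, "pair": [u, v], "wanted": want, "allocated": got}
                )
    new_map = LandUseMap(lu.grid.with_values(values), lu.legend)
    return CAState(new_map, remaining, allocated, state.cycle + 1)


def simulate(
    base: LandUseMap,
    P: TransitionMatrix,
    atlas: SuitabilityAtlas,
    config: CAConfig,
) -> tuple[LandUseMap, dict]:
    """Project one Markov step and allocate it over ``config.cycles`` cycles.

    Returns the simulated map and a run log (seed, per-cycle shortfalls,
    final allocation per pair). Cell counts are conserved exactly; frozen
    cells are bit-identical to the base map.
    """
    for code in base.codes:
        if code not in atlas.rasters:
            raise ValueError(f"atlas missing class {code}")
        if not atlas[code].aligned_with(base.grid):
            raise ValueError("atlas not aligned with base map")
    totals = pair_demands(P, base_counts=[base.class_counts()[c] for c in P.codes])
    shortfall_log: list = []
    state = CAState(base, remaining=dict(totals))
    T = config.cycles
    for t in range(1, T + 1):
        quota = _cycle_quota(totals, state.allocated, t, T)
        state = allocate_cycle(state, atlas, quota, config, log=shortfall_log)
    run_log = {
        "seed": config.seed,
        "scenario": config.scenario,
        "cycles": T,
        "filter": config.filter_size,
        "demand": {f"{u}->{v}": n for (u, v), n in totals.items()},
        "allocated": {f"{u}->{v}": n for (u, v), n in state.allocated.items()},
        "shortfalls": shortfall_log,
    }
    return state.landuse, run_log
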