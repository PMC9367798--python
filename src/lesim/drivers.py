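"""Constraint-factor weighting by binary logistic regression.

For each land class, presence (1) / absence (0) is sampled from the map,
driver values are extracted at the sampled cells, collinearity among
drivers is screened by variance inflation factors, a logit model is fit
on z-scored drivers, and non-significant factors are dropped. The
remaining factors receive weights proportional to the magnitude of their
standardized coefficients (normalized to unit sum), with the coefficient
sign carried separately so the suitability stage can orient each fuzzy
factor (e.g., construction suitability falling with slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import RasterGrid, LandUseMap, check_aligned

__all__ = [
    "DriverStack",
    "BLRResult",
    "sample_points",
    "extract_values",
    "collinearity",
    "fit_blr",
    "derive_weights",
    "fit_class_weights",
]


@dataclass
class DriverStack:
    """Named continuous driver rasters, all aligned to the land-use grid."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("empty driver stack")
        if not check_aligned(list(self.layers.values())):
            raise ValueError("driver layers are not aligned")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def aligned_with(self, grid: RasterGrid) -> bool:
        return next(iter(self.layers.values())).aligned_with(grid)


@dataclass
class BLRResult:
    """Per-class regression outcome: coefficients, screening, and weights.

    ``table`` has one row per driver with columns coefficient, p_value,
    vif, tol, weight, sign ('+', '-', or '—' for dropped factors).
    """

    land_class: int
    period: str
    table: pd.DataFrame
    separation: bool = False
    converged: bool = True
    n_samples: int = 0

    @property
    def weights(self) -> pd.Series:
        kept = self.table[self.table["weight"] > 0]
        return kept.set_index("factor")["weight"]

    @property
    def signs(self) -> pd.Series:
        kept = self.table[self.table["weight"] > 0]
        return kept.set_index("factor")["sign"]


def sample_points(
    landuse: LandUseMap, land_class: int, fraction: float, seed: int
) -> pd.DataFrame:
    """Stratified presence/absence sample of cells for one land class.

    Draws ``floor(fraction * n1)`` cells of the class (label 1) and
    ``floor(fraction * n0)`` other non-nodata cells (label 0), uniformly
    without replacement within each stratum, reproducibly by ``seed``.
    Returns columns row, col, label.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mask = landuse.grid.mask
    pres = np.argwhere((landuse.grid.values == land_class) & mask)
    absn = np.argwhere((landuse.grid.values != land_class) & mask)
    if len(pres) == 0:
        raise ValueError(f"class {land_class} absent from map")
    n1 = int(fraction * len(pres))
    n0 = int(fraction * len(absn))
    if n1 == 0 or n0 == 0:
        raise ValueError("fraction yields an empty stratum")
    rng = np.random.default_rng(seed)
    take1 = pres[rng.choice(len(pres), size=n1, replace=False)]
    take0 = absn[rng.choice(len(absn), size=n0, replace=False)]
    rows = np.concatenate([take1, take0])
    labels = np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)])
    return pd.DataFrame({"row": rows[:, 0], "col": rows[:, 1], "label": labels})


def extract_values(stack: DriverStack, sample: pd.DataFrame) -> pd.DataFrame:
    """Append one column per driver with values at the sampled cells."""
    out = sample.copy()
    r, c = sample["row"].to_numpy(), sample["col"].to_numpy()
    for name, grid in stack.layers.items():
        out[name] = grid.values[r, c].astype(float)
    return out


def collinearity(x: pd.DataFrame, factors: list[str] | None = None) -> pd.DataFrame:
    """Variance inflation factor and tolerance per driver.

    VIF_j = 1/(1 - R^2_j) from the least-squares regression of factor j on
    the other factors (with intercept); TOL_j = 1/VIF_j. Factors with
    VIF >= 10 (including infinite VIF from exact collinearity) are flagged.
    """
    factors = factors or [c for c in x.columns if c not in {"row", "col", "label"}]
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    X = x[factors].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(factors) + 1:
        raise ValueError("sample too small for collinearity screening")
    rows = []
    for j, name in enumerate(factors):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 0.0 if sst == 0 else 1.0 - resid @ resid / sst
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"factor": name, "vif": vif, "tol": 1.0 / vif, "flagged": vif >= 10})
    return pd.DataFrame(rows)


def fit_blr(
    sample: pd.DataFrame,
    factors: list[str],
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[pd.Series, pd.Series, dict]:
    """Maximum-likelihood logit fit on z-scored factors.

    Returns (coefficients, p_values, info). Factors are standardized so
    coefficient magnitudes are comparable across measurement units. On
    perfect separation or non-convergence the model is refit with a small
    ridge penalty (1e-6) and flagged; penalized coefficients carry p-value
    0 (the separating factor is unambiguously associated).
    """
    y = sample["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("sample must contain both labels")
    X = sample[factors].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = sm.add_constant((X - mu) / sd, has_constant="add")
    info = {"separation": False, "converged": True, "n": len(y)}
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Z).fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
        if not res.mle_retvals.get("converged", True) or np.any(~np.isfinite(res.bse)):
            raise RuntimeError("logit did not converge")
        coefs = pd.Series(res.params[1:], index=factors)
        pvals = pd.Series(res.pvalues[1:], index=factors)
    except Exception:
        info["separation"] = True
        with np.errstate(all="ignore"):
            res = sm.GLM(y, Z, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-6, L1_wt=0.0
            )
        coefs = pd.Series(np.asarray(res.params)[1:], index=factors)
        pvals = pd.Series(0.0, index=factors)
    return coefs, pvals, info


def derive_weights(
    coefficients: pd.Series, p_values: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Signed unit-sum weights from standardized logit coefficients.

    Factors with p >= alpha are dropped (sign '—', weight 0); survivors
    get weight |coef| / sum |coef| and sign from the coefficient. Scale
    invariant: multiplying all coefficients by c > 0 changes nothing.
    """
    keep = p_values < alpha
    mags = coefficients[keep].abs()
    if mags.sum() == 0:
        raise ValueError("no significant factors")
    rows = []
    for f in coefficients.index:
        if keep[f] and abs(coefficients[f]) > 0:
            rows.append(
                {
                    "factor": f,
                    "coefficient": coefficients[f],
                    "p_value": p_values[f],
                    "weight": abs(coefficients[f]) / mags.sum(),
                    "sign": "+" if coefficients[f] > 0 else "-",
                }
            )
        else:
            rows.append(
                {
                    "factor": f,
                    "coefficient": coefficients[f],
                    "p_value": p_values[f],
                    "weight": 0.0,
                    "sign": "—",
                }
            )
    return pd.DataFrame(rows)


def fit_class_weights(
    landuse: LandUseMap,
    stack: DriverStack,
    land_class: int,
    fraction: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
    period: str = "T",
    include: list[str] | None = None,
) -> BLRResult:
    """Full per-class pipeline: sample -> screen -> fit -> weights.

    ``include`` restricts the candidate factor list a priori (some factors
    may be excluded for a class before fitting). Presence is sampled from
    the supplied (period-end) map.
    """
    if not stack.aligned_with(landuse.grid):
        raise ValueError("driver stack not aligned with land-use map")
    factors = include or stack.names
    sample = extract_values(stack, sample_points(landuse, land_class, fraction, seed))
    vif = collinearity(sample, factors).set_index("factor")
    coefs, pvals, info = fit_blr(sample, factors)
    weights = derive_weights(coefs, pvals, alpha=alpha)
    weights["vif"] = weights["factor"].map(vif["vif"])
    weights["tol"] = weights["factor"].map(vif["tol"])
    weights.insert(0, "period", period)
    weights.insert(0, "land_class", land_class)
    return BLRResult(
        land_class=land_class,
        period=period,
        table=weights,
        separation=info["separation"],
        converged=info["converged"],
        n_samples=info["n"],
    )
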