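"""Land ecological security index (LESI) via the catastrophe progression method.

The index is computed per grid unit from a pressure-state-response (PSR)
indicator table in four steps:

1. **Standardization** — each indicator is min-max scaled over units; a
   *positive* indicator (more is safer) maps its maximum to 1, a *negative*
   one (more is riskier) maps its maximum to 0.
2. **Entropy weighting** — indicator importance grows with dispersion
   across units; weights are used only to *rank* siblings, never as
   multiplicative weights.
3. **Catastrophe-progression aggregation** — the indicator hierarchy is
   folded bottom-up: the k-th most important child of a node (k = 1..4)
   is normalized as value**(1/(k+1)) — square root for the leading control
   variable, cube root for the second, and so on — and siblings are
   combined by their mean (complementary principle) or minimum
   (non-complementary).
4. **Index adjustment** — raw CPM scores crowd near 1, so the raw index
   L is re-expressed against reference levels n_i obtained by aggregating
   the hierarchy with all leaves at i/10 (i = 0..10). Within the bracket
   [n_i, n_i+1] the adjusted value is (L - n_i)/(n_i+1 - n_i) * 0.1; the
   default ``monotone`` variant adds the decile offset i*0.1 so the
   adjusted index stays globally order-preserving on [0, 1], while the
   ``verbatim`` variant omits the offset (every decile collapses onto
   [0, 0.1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorTable",
    "CPMNode",
    "CPMHierarchy",
    "MODEL_BY_ARITY",
    "standardize",
    "entropy_weights",
    "rank_children",
    "cpm_aggregate",
    "reference_levels",
    "adjust_index",
    "default_psr_hierarchy",
    "DEFAULT_PSR_WEIGHTS",
    "load_hierarchy",
    "read_indicator_table",
]

#: Catastrophe model implied by the number of control variables.
MODEL_BY_ARITY = {1: "fold", 2: "cusp", 3: "swallowtail", 4: "butterfly"}


@dataclass
class IndicatorTable:
    """Per-unit indicator values with positive/negative attributes.

    ``values`` is a (units x indicators) DataFrame indexed by unit id;
    ``attributes`` maps each indicator to ``'positive'`` or ``'negative'``;
    ``standardized`` holds the min-max standardized values once
    :func:`standardize` has run.
    """

    values: pd.DataFrame
    attributes: dict[str, str]
    standardized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least 2 units")
        missing = set(self.values.columns) - set(self.attributes)
        if missing:
            raise ValueError(f"indicators without attribute: {sorted(missing)}")
        bad = {a for a in self.attributes.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"invalid attributes: {sorted(bad)}")
        if self.standardized is not None:
            s = self.standardized.to_numpy(dtype=float)
            if np.nanmin(s) < -1e-12 or np.nanmax(s) > 1 + 1e-12:
                raise ValueError("standardized values must lie in [0, 1]")

    @property
    def unit_ids(self):
        return self.values.index

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)


def standardize(table: IndicatorTable) -> IndicatorTable:
    """Min-max standardize every indicator over units.

    Positive: H = (x - min)/(max - min). Negative: H = (max - x)/(max - min).
    A constant column is an error (zero information, undefined scaling).
    """
    x = table.values
    lo, hi = x.min(axis=0), x.max(axis=0)
    constant = hi <= lo
    if constant.any():
        raise ValueError(
            f"constant indicator column(s): {list(x.columns[constant])}"
        )
    h = (x - lo) / (hi - lo)
    for name, attr in table.attributes.items():
        if name in h.columns and attr == "negative":
            h[name] = 1.0 - h[name]
    return IndicatorTable(table.values, dict(table.attributes), standardized=h)


def entropy_weights(table: IndicatorTable) -> pd.Series:
    """Entropy-method importance weights over indicators.

    p_ij = H_ij / sum_i H_ij, e_j = -(1/ln m) sum_i p ln p (0 ln 0 := 0),
    w_j = (1 - e_j) / sum_k (1 - e_k). A column constant across units
    carries no information and gets weight 0; columns summing to 0 are
    shifted by 1e-4 before proportioning.
    """
    if table.standardized is None:
        raise ValueError("standardize the table first")
    h = table.standardized.to_numpy(dtype=float).copy()
    m = h.shape[0]
    col_sums = h.sum(axis=0)
    h[:, col_sums == 0] += 1e-4
    p = h / h.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    d = 1.0 - e
    d = np.where(d < 0, 0.0, d)  # guard fp noise for constant columns
    if d.sum() == 0:
        raise ValueError("all indicators constant: entropy weights undefined")
    w = d / d.sum()
    return pd.Series(w, index=table.standardized.columns, name="weight")


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------


@dataclass
class CPMNode:
    """A node of the aggregation tree.

    Leaves name indicators; internal nodes combine 1-4 children whose
    order (after ranking) maps to control variables a, b, c, d. The
    ``principle`` is 'complementary' (mean) or 'non-complementary' (min).
    """

    name: str
    children: list["CPMNode"] = field(default_factory=list)
    principle: str = "complementary"
    weight: float | None = None  # leaves: fixed entropy weight, if declared

    def __post_init__(self) -> None:
        if self.children and len(self.children) > 4:
            raise ValueError(
                f"node {self.name!r}: {len(self.children)} children; "
                "catastrophe models support at most 4 control variables"
            )
        if self.principle not in {"complementary", "non-complementary"}:
            raise ValueError(f"node {self.name!r}: unknown principle {self.principle!r}")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def model(self) -> str | None:
        return None if self.is_leaf else MODEL_BY_ARITY[len(self.children)]

    def leaves(self) -> list["CPMNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class CPMHierarchy:
    """The full aggregation tree, rooted at the overall objective."""

    root: CPMNode

    def leaves(self) -> list[CPMNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def declared_weights(self) -> dict[str, float]:
        return {l.name: l.weight for l in self.leaves() if l.weight is not None}


def _node_importance(node: CPMNode, weights: dict[str, float]) -> float:
    """Importance of a node = sum of its descendant leaf weights."""
    return sum(weights[leaf.name] for leaf in node.leaves())


def rank_children(hierarchy: CPMHierarchy, weights) -> CPMHierarchy:
    """Reorder every node's children by descending importance.

    The first child after ranking maps to control variable a (exponent
    1/2), the second to b (1/3), etc. Ties keep declaration order
    (stable sort).
    """
    w = dict(weights) if not isinstance(weights, dict) else weights
    missing = set(hierarchy.leaf_names()) - set(w)
    if missing:
        raise ValueError(f"leaves without weight: {sorted(missing)}")

    def rank(node: CPMNode) -> CPMNode:
        if node.is_leaf:
            return CPMNode(node.name, [], node.principle, node.weight)
        ranked = [rank(c) for c in node.children]
        ranked.sort(key=lambda c: -_node_importance(c, w))
        return CPMNode(node.name, ranked, node.principle, node.weight)

    return CPMHierarchy(rank(hierarchy.root))


def cpm_aggregate(hierarchy: CPMHierarchy, leaf_values) -> np.ndarray | float:
    """Fold the hierarchy bottom-up to the raw index L per unit.

    ``leaf_values`` is a standardized :class:`IndicatorTable`, a DataFrame
    of H values (units x leaf columns), a mapping leaf -> value, or a
    scalar applied to every leaf. Child k (1-based rank) is normalized as
    v**(1/(k+1)); siblings combine by mean (complementary) or min.
    """
    if isinstance(leaf_values, IndicatorTable):
        if leaf_values.standardized is None:
            raise ValueError("standardize the table first")
        frame = leaf_values.standardized
    elif isinstance(leaf_values, pd.DataFrame):
        frame = leaf_values
    elif np.isscalar(leaf_values):
        frame = None
        scalar = float(leaf_values)
        leaf_values = {name: scalar for name in hierarchy.leaf_names()}
    else:
        frame = None

    def value_of(leaf: CPMNode) -> np.ndarray:
        if frame is not None:
            v = frame[leaf.name].to_numpy(dtype=float)
        else:
            v = np.asarray(leaf_values[leaf.name], dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError(f"leaf {leaf.name!r} outside [0, 1]")
        return np.clip(v, 0.0, 1.0)

    def fold(node: CPMNode) -> np.ndarray:
        if node.is_leaf:
            return value_of(node)
        normalized = [
            fold(child) ** (1.0 / (k + 1))
            for k, child in enumerate(node.children, start=1)
        ]
        stack = np.stack(np.broadcast_arrays(*normalized)) if len(normalized) > 1 \
            else np.asarray(normalized)
        if node.principle == "complementary":
            return stack.mean(axis=0)
        return stack.min(axis=0)

    result = fold(hierarchy.root)
    return float(result) if np.ndim(result) == 0 else result


def reference_levels(hierarchy: CPMHierarchy) -> np.ndarray:
    """Reference levels n_i, i = 0..10: aggregate with all leaves at i/10.

    n_0 = 0, n_10 = 1, strictly increasing — the CPM folding is strictly
    monotone in any leaf, so uniform leaf levels map to increasing roots.
    """
    levels = np.array([float(cpm_aggregate(hierarchy, i / 10)) for i in range(11)])
    if not np.all(np.diff(levels) > 0):
        raise ValueError("reference levels are not strictly increasing")
    return levels


def adjust_index(L, levels: np.ndarray, variant: str = "monotone") -> np.ndarray:
    """Re-express raw CPM indices against the reference levels.

    Each L in [n_i, n_i+1] becomes (L - n_i)/(n_i+1 - n_i) * 0.1, plus the
    decile offset i*0.1 under the default ``monotone`` variant (globally
    order-preserving, range [0, 1]); the ``verbatim`` variant omits the
    offset, collapsing every decile onto [0, 0.1].
    """
    if variant not in {"monotone", "verbatim"}:
        raise ValueError("variant must be 'monotone' or 'verbatim'")
    L = np.asarray(L, dtype=float)
    if np.any(L < -1e-12) or np.any(L > 1 + 1e-12):
        raise ValueError("raw index outside [0, 1]")
    Lc = np.clip(L, 0.0, 1.0)
    # interval i such that n_i <= L < n_{i+1}; an exact hit on a level
    # starts its own interval (L = n_i -> fraction 0), except L = n_10 = 1
    # which closes the top interval at fraction 0.1
    i = np.searchsorted(levels, Lc, side="right") - 1
    i = np.clip(i, 0, 9)
    lo, hi = levels[i], levels[i + 1]
    frac = (Lc - lo) / (hi - lo) * 0.1
    out = frac + (i * 0.1 if variant == "monotone" else 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Default PSR hierarchy: 3 criteria / 9 factors / 19 indicators
# ---------------------------------------------------------------------------

#: Published entropy weights for the 19 PSR indicators, shipped as the
#: default ranking fixture (indicator code -> weight; weights sum to 1).
DEFAULT_PSR_WEIGHTS: dict[str, float] = {
    "D1": 0.005, "D2": 0.012, "D3": 0.034, "D4": 0.029, "D5": 0.074,
    "D6": 0.021, "D7": 0.082, "D8": 0.138, "D9": 0.091, "D10": 0.041,
    "D11": 0.045, "D12": 0.024, "D13": 0.074, "D14": 0.015, "D15": 0.009,
    "D16": 0.072, "D17": 0.085, "D18": 0.043, "D19": 0.106,
}

#: Attribute (orientation) of each default indicator.
DEFAULT_PSR_ATTRIBUTES: dict[str, str] = {
    "D1": "negative", "D2": "negative", "D3": "negative", "D4": "negative",
    "D5": "negative", "D6": "negative", "D7": "positive", "D8": "positive",
    "D9": "negative", "D10": "negative", "D11": "positive", "D12": "positive",
    "D13": "positive", "D14": "positive", "D15": "positive", "D16": "negative",
    "D17": "positive", "D18": "positive", "D19": "positive",
}

_DEFAULT_STRUCTURE = {
    "B1": {"C1": ["D1", "D2"], "C2": ["D3", "D4"], "C3": ["D5", "D6"]},
    "B2": {"C4": ["D7", "D8"], "C5": ["D9", "D10"], "C6": ["D11", "D12", "D13"]},
    "B3": {"C7": ["D14", "D15"], "C8": ["D16", "D17"], "C9": ["D18", "D19"]},
}


def default_psr_hierarchy(with_weights: bool = True) -> CPMHierarchy:
    """The standard pressure-state-response tree.

    Three criteria (pressure B1, state B2, response B3), nine factors
    (C1-C9), nineteen indicators (D1-D19). Leaf weights default to the
    published entropy weights so the tree can be ranked out of the box.
    """
    criteria = []
    for b, factors in _DEFAULT_STRUCTURE.items():
        fnodes = []
        for c, inds in factors.items():
            leaves = [
                CPMNode(d, weight=DEFAULT_PSR_WEIGHTS[d] if with_weights else None)
                for d in inds
            ]
            fnodes.append(CPMNode(c, leaves))
        criteria.append(CPMNode(b, fnodes))
    return CPMHierarchy(CPMNode("A", criteria))


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def _node_from_dict(spec) -> CPMNode:
    if isinstance(spec, str):
        return CPMNode(spec)
    name = spec["name"]
    children = [_node_from_dict(c) for c in spec.get("children", [])]
    return CPMNode(
        name,
        children,
        principle=spec.get("principle", "complementary"),
        weight=spec.get("weight"),
    )


def load_hierarchy(path: str | Path) -> CPMHierarchy:
    """Load a hierarchy from YAML.

    Schema: a node is either an indicator name (string) or a mapping with
    ``name``, optional ``children`` (list of nodes), optional ``principle``
    and ``weight``.
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return CPMHierarchy(_node_from_dict(spec))


def read_indicator_table(values_csv: str | Path, attributes_csv: str | Path) -> IndicatorTable:
    """Read an indicator table from a values CSV and an attribute sidecar.

    Values CSV: header ``unit_id, <indicator...>``. Attribute CSV: columns
    ``indicator, attribute`` (plus optional ``weight``).
    """
    values = pd.read_csv(values_csv).set_index("unit_id")
    attrs = pd.read_csv(attributes_csv)
    attributes = dict(zip(attrs["indicator"], attrs["attribute"]))
    return IndicatorTable(values, attributes)
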