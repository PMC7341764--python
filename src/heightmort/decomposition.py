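"""Compositional decomposition of pooled mortality across height classes.

For height class i with taxonomic groups t = 1..x, pooled fractional
mortality is equivalently the count form

    M_i = (sum_t d_it) / (sum_t n_it)

or the composition-weighted form

    M_i = sum_t m_it * p_it,      m_it = d_it / n_it,  p_it = n_it / sum_t n_it,

with sum_t p_it = 1. Because M_i is a convex combination of the group
mortalities, a pooled trend across height classes can run opposite to
every group's own trend when the proportions p shift with height
(Simpson's paradox). Two counterfactual standardizations isolate that
mechanism:

* constant composition -- recompute M_i with a single reference
  proportion vector (e.g. the population as a whole) in every class,
  keeping each class's actual group mortalities;
* constant group mortality -- recompute M_i with the actual proportions
  but one focal group's mortality pinned to its pooled (all-heights)
  value in every class.

All inputs are real-valued: populations back-calculated from posterior
mortalities are non-integer by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLS = ("height_class", "group", "n", "d")


def _pivot(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(n, d) matrices, height classes x groups, preserving first-seen order."""
    missing = [c for c in REQUIRED_COLS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns {missing}")
    if (counts["n"] < 0).any() or (counts["d"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts["d"] > counts["n"] + 1e-9).any():
        raise ValueError("deaths d cannot exceed population n in any cell")
    classes = list(pd.unique(counts["height_class"]))
    groups = list(pd.unique(counts["group"]))
    n = counts.pivot_table(index="height_class", columns="group", values="n",
                           fill_value=0.0, aggfunc="sum").reindex(index=classes, columns=groups)
    d = counts.pivot_table(index="height_class", columns="group", values="d",
                           fill_value=0.0, aggfunc="sum").reindex(index=classes, columns=groups)
    return n.astype(float), d.astype(float)


def pooled_mortality(counts: pd.DataFrame) -> pd.Series:
    """Pooled M per height class from the count form (total d / total n)."""
    n, d = _pivot(counts)
    tot = n.sum(axis=1)
    if (tot <= 0).any():
        bad = tot.index[tot <= 0].tolist()
        raise ValueError(f"height classes with zero population: {bad}")
    return (d.sum(axis=1) / tot).rename("M")


def proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Group proportions p_it per height class (rows sum to 1)."""
    n, _ = _pivot(counts)
    tot = n.sum(axis=1)
    if (tot <= 0).any():
        raise ValueError("cannot form proportions for a class with zero population")
    return n.div(tot, axis=0)


def group_mortalities(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fractional mortality m_it = d/n (0 where the cell is empty)."""
    n, d = _pivot(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = d / n
    return m.where(n > 0, 0.0)


def decomposition_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Long table of p, m, n, d per cell plus the class's pooled M."""
    p = proportions(counts)
    m = group_mortalities(counts)
    big_m = pooled_mortality(counts)
    n, d = _pivot(counts)
    rows = []
    for hc in p.index:
        for g in p.columns:
            rows.append({"height_class": hc, "group": g, "n": n.loc[hc, g],
                         "d": d.loc[hc, g], "p": p.loc[hc, g], "m": m.loc[hc, g],
                         "M": big_m.loc[hc]})
    return pd.DataFrame(rows)


def pooled_reference_proportions(counts: pd.DataFrame) -> pd.Series:
    """Whole-population proportions (all height classes combined), by group."""
    n, _ = _pivot(counts)
    tot = n.sum().sum()
    if tot <= 0:
        raise ValueError("empty counts table")
    return n.sum(axis=0) / tot


def _reference_series(reference_p, groups) -> pd.Series:
    ref = pd.Series(reference_p) if not isinstance(reference_p, pd.Series) else reference_p
    if not isinstance(reference_p, pd.Series) and len(ref) == len(groups):
        # positional vector: adopt the table's group order
        if not all(isinstance(i, str) and i in groups for i in ref.index):
            ref.index = groups
    if set(ref.index) != set(groups):
        raise ValueError(
            f"reference proportions groups {sorted(map(str, ref.index))} "
            f"do not match table groups {sorted(map(str, groups))}")
    ref = ref.reindex(groups).astype(float)
    if abs(ref.sum() - 1.0) > 1e-9:
        raise ValueError(f"reference proportions must sum to 1 (got {ref.sum()})")
    return ref


def standardize_composition(counts: pd.DataFrame, reference_p) -> pd.Series:
    """Hypothetical M per class under a fixed reference composition.

    Keeps each class's actual group mortalities but weights them by
    ``reference_p`` instead of the class's own proportions.
    """
    m = group_mortalities(counts)
    ref = _reference_series(reference_p, list(m.columns))
    return (m * ref).sum(axis=1).rename("M_standardized")


def standardize_group_mortality(counts: pd.DataFrame, group: str,
                                pooled_m: float | None = None) -> pd.Series:
    """Hypothetical M per class with one group's mortality held constant.

    Uses the actual proportions and the actual mortalities of every other
    group, but replaces ``group``'s mortality in each class with
    ``pooled_m`` (default: the group's own all-heights pooled mortality).
    """
    n, d = _pivot(counts)
    if group not in n.columns:
        raise KeyError(f"group {group!r} not present in counts table")
    if pooled_m is None:
        gn = n[group].sum()
        if gn <= 0:
            raise ValueError(f"group {group!r} has zero population; supply pooled_m")
        pooled_m = float(d[group].sum() / gn)
    if not 0.0 <= pooled_m <= 1.0:
        raise ValueError("pooled_m must lie in [0, 1]")
    p = proportions(counts)
    m = group_mortalities(counts).copy()
    m[group] = pooled_m
    return (m * p).sum(axis=1).rename("M_constant_group")


def trend_direction(values, tol: float = 1e-9) -> str:
    """Classify a sequence as increasing / decreasing / constant / non-monotone.

    Strict comparisons with a float tolerance: steps within ``tol`` of zero
    count as ties; any tie demotes a strict trend to non-monotone unless
    all steps are ties (constant).
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 height classes to classify a trend")
    diffs = np.diff(v)
    if np.all(np.abs(diffs) <= tol):
        return "constant"
    if np.all(diffs > tol):
        return "increasing"
    if np.all(diffs < -tol):
        return "decreasing"
    return "non-monotone"


_OPPOSITE = {"increasing": "decreasing", "decreasing": "increasing"}


def detect_simpson_reversal(counts: pd.DataFrame, tol: float = 1e-9,
                            majority: float = 0.9) -> dict:
    """Flag a composition-driven reversal between group and pooled trends.

    A reversal is declared when the pooled M sequence is strictly monotone
    while groups holding at least ``majority`` of all trees trend strictly
    in the opposite direction. When groups disagree among themselves
    (one increasing, one decreasing), the report flags
    ``opposing_group_trends`` instead.
    """
    m = group_mortalities(counts)
    if len(m.index) < 2:
        raise ValueError("need at least 2 height classes")
    n, _ = _pivot(counts)
    weights = n.sum(axis=0) / n.sum().sum()
    group_dir = {g: trend_direction(m[g].to_numpy(), tol) for g in m.columns}
    pooled_dir = trend_direction(pooled_mortality(counts).to_numpy(), tol)
    opposite = _OPPOSITE.get(pooled_dir)
    opp_weight = float(sum(weights[g] for g, dr in group_dir.items() if dr == opposite))
    dirs = set(group_dir.values())
    return {
        "group_directions": group_dir,
        "pooled_direction": pooled_dir,
        "opposite_trend_weight": opp_weight,
        "reversal": opposite is not None and opp_weight >= majority,
        "opposing_group_trends": {"increasing", "decreasing"} <= dirs,
    }
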