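"""From cluster labels to ordered risk levels and ranked reports.

Clusters coming out of spectral clustering are unordered; risk levels must
be ordinal (1 = lowest risk ... k = highest). Each cluster is scored by the
mean, over its members, of the composite standardized risk
``z(pc) + z(hi) - z(moe)`` — higher pollution and hazard raise risk, a wider
margin of exposure lowers it — and clusters are ranked ascending by that
score to receive levels 1..k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .spectral import ClusterAssignment

__all__ = [
    "composite_scores",
    "order_clusters_by_risk",
    "assign_levels",
    "level_proportions",
    "rank_high_risk",
    "exceedance_factor",
]


def composite_scores(Z: np.ndarray) -> np.ndarray:
    """Per-row composite risk score z(pc) + z(hi) - z(moe) from the
    standardized (pc, hi, moe) matrix."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 3:
        raise DomainError("expected an n x 3 standardized (pc, hi, moe) matrix")
    return Z[:, 0] + Z[:, 1] - Z[:, 2]


def order_clusters_by_risk(Z: np.ndarray, labels: np.ndarray) -> dict[int, int]:
    """Map cluster id -> ordinal risk level (1 = lowest composite risk).

    Clusters are sorted by mean member composite score; exact ties break by
    cluster size descending, then cluster id, so the mapping is
    deterministic.
    """
    labels = np.asarray(labels)
    scores = composite_scores(Z)
    if labels.shape[0] != scores.shape[0]:
        raise DomainError("labels and feature rows must align")
    records = []
    for cid in np.unique(labels):
        members = labels == cid
        records.append((float(scores[members].mean()), -int(members.sum()), int(cid)))
    records.sort()
    return {cid: level for level, (_, _, cid) in enumerate(records, start=1)}


def assign_levels(
    combinations: pd.DataFrame,
    assignment: ClusterAssignment,
    level_map: dict[int, int],
    Z: np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the per-combination risk-level table (region-major order).

    ``combinations`` must carry region/category rows aligned with
    ``assignment.labels``. If the standardized matrix ``Z`` is given, the
    per-combination composite score is attached as ``risk_score`` (used for
    within-level ordering of the high-risk report).
    """
    labels = assignment.labels
    if len(combinations) != len(labels):
        raise DomainError("combination table and labels must align")
    uncovered = set(np.unique(labels)) - set(level_map)
    if uncovered:
        raise DomainError(f"level map does not cover cluster id(s) {sorted(uncovered)}")
    out = combinations[["region", "category"]].copy()
    out["cluster_id"] = labels
    out["risk_level"] = [level_map[int(c)] for c in labels]
    if Z is not None:
        out["risk_score"] = composite_scores(Z)
    return out.sort_values(["region", "category"], ignore_index=True)


def level_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level counts and percentages plus the low (1-2) / high (4-5) groupings.

    Percentages are reported to 2 decimals and sum to 100 within rounding.
    """
    if table.empty:
        raise DomainError("risk-level table is empty")
    n = len(table)
    counts = table["risk_level"].value_counts().sort_index()
    # largest-remainder rounding so the per-level percentages sum to 100.00
    raw = 100.0 * counts.to_numpy(float) / n
    floored = np.floor(raw * 100) / 100
    shortfall = int(round((100.0 - floored.sum()) * 100))
    order = np.argsort(-(raw * 100 - np.floor(raw * 100)), kind="stable")
    for idx in order[:shortfall]:
        floored[idx] += 0.01
    rows = [
        {"group": str(level), "count": int(c), "percent": round(p, 2)}
        for (level, c), p in zip(counts.items(), floored)
    ]
    low = int(table["risk_level"].isin([1, 2]).sum())
    high = int(table["risk_level"].isin([4, 5]).sum())
    rows.append({"group": "levels 1-2", "count": low, "percent": round(100.0 * low / n, 2)})
    rows.append({"group": "levels 4-5", "count": high, "percent": round(100.0 * high / n, 2)})
    return pd.DataFrame(rows)


def rank_high_risk(
    table: pd.DataFrame,
    threshold_level: int = 3,
    limits: pd.DataFrame | None = None,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combinations at or above ``threshold_level``, highest risk first.

    Sorted by level descending, ties by composite ``risk_score`` descending
    when present. If the limit table and combination summaries are supplied,
    an ``exceedance_factor`` column (max concentration over the limit) is
    attached.
    """
    out = table[table["risk_level"] >= threshold_level].copy()
    sort_cols = ["risk_level"]
    if "risk_score" in out.columns:
        sort_cols.append("risk_score")
    out = out.sort_values(sort_cols, ascending=False, ignore_index=True)
    if limits is not None and stats is not None:
        s_map = dict(limits[["category", "limit_mg_per_kg"]].itertuples(index=False))
        max_map = {
            (r, c): m for r, c, m in stats[["region", "category", "max"]].itertuples(index=False)
        }
        out["exceedance_factor"] = [
            exceedance_factor(max_map[(r, c)], s_map[c])
            for r, c in zip(out["region"], out["category"])
        ]
    return out


def exceedance_factor(x_max: float, s: float) -> float:
    """How many times the highest sample exceeds the regulatory limit (X_max/S)."""
    if s <= 0:
        raise DomainError(f"limit must be positive, got {s}")
    if x_max < 0:
        raise DomainError(f"concentration must be non-negative, got {x_max}")
    return x_max / s
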