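"""Outlier detection and structure/property consistency screening.

A database is internally consistent when structurally similar entries carry
similar property values.  The screen cuts the cluster tree at a fixed
linkage height and, for every cluster, compares the structural spread σ_D
(RMS distance to the representative) with the property spread σ_E (population
standard deviation of, e.g., the energy).  Clusters that are structurally
tight but energetically wild — σ_D below ``sigma_D_max`` while σ_E exceeds
``sigma_E_min`` — are the signature of inconsistent data (σ_E converging to
a non-zero constant as σ_D shrinks) and are flagged.  The thresholds are
deliberately user-set: the (σ_D, σ_E) scatter itself is part of the report.

Outlier scanning walks the dendrogram from the root and returns the small
branches (≤ ``max_size`` members) that merge into the rest of the database
at a linkage height ≥ ``min_height``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hcluster import Cluster, ClusterTree, cut, representative, spread
from .rematch import DistanceMatrix

__all__ = [
    "ConsistencyRecord",
    "property_spread",
    "consistency_screen",
    "outlier_scan",
    "screen_report",
]


@dataclass
class ConsistencyRecord:
    """Per-cluster (σ_D, σ_E) entry of the consistency screen."""

    cluster: Cluster
    sigma_D: float
    sigma_E: float
    flagged: bool
    reason: str  # "inconsistent" | "outlier" | "none"

    def __post_init__(self) -> None:
        if self.reason not in ("inconsistent", "outlier", "none"):
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.flagged != (self.reason != "none"):
            raise ValueError("flagged must mirror reason != 'none'")


def property_spread(
    members: Sequence[str],
    values: Mapping[str, float],
    mode: str = "sd",
    rep: str | None = None,
) -> float:
    """Spread σ_E of a property over cluster members.

    ``mode='sd'`` (default): population standard deviation about the cluster
    mean.  ``mode='rms_about_rep'``: RMS deviation from the representative's
    value (requires ``rep``).
    """
    vals = []
    for m in members:
        if m not in values:
            raise KeyError(f"no property value for structure {m!r}")
        vals.append(values[m])
    v = np.asarray(vals, dtype=float)
    if mode == "sd":
        return float(np.sqrt(np.mean((v - v.mean()) ** 2)))
    if mode == "rms_about_rep":
        if rep is None:
            raise ValueError("mode='rms_about_rep' requires rep")
        if rep not in values:
            raise KeyError(f"no property value for representative {rep!r}")
        return float(np.sqrt(np.mean((v - values[rep]) ** 2)))
    raise ValueError(f"unknown mode {mode!r}")


def consistency_screen(
    tree: ClusterTree,
    D: DistanceMatrix | np.ndarray,
    values: Mapping[str, float],
    cut_height: float = 0.1,
    sigma_D_max: float = np.inf,
    sigma_E_min: float = np.inf,
    spread_mode: str = "sd",
) -> list[ConsistencyRecord]:
    """Cut the tree and flag structurally-tight, property-wild clusters.

    Returns one record per cluster of the cut (singletons included with zero
    spreads, so record sizes partition the dataset); a cluster of ≥ 2 members
    is flagged ``inconsistent`` when σ_D < sigma_D_max and σ_E > sigma_E_min.
    """
    if cut_height < 0:
        raise ValueError("cut_height must be >= 0")
    if sigma_D_max <= 0 or sigma_E_min <= 0:
        raise ValueError("thresholds must be > 0")
    records: list[ConsistencyRecord] = []
    for c in cut(tree, cut_height):
        c.representative_id = representative(c.member_ids, D)
        c.spread = spread(c.member_ids, c.representative_id, D)
        if len(c) < 2:
            c.property_spread = 0.0
            records.append(ConsistencyRecord(c, 0.0, 0.0, False, "none"))
            continue
        sig_e = property_spread(
            c.member_ids, values, mode=spread_mode, rep=c.representative_id
        )
        c.property_spread = sig_e
        flag = c.spread < sigma_D_max and sig_e > sigma_E_min
        records.append(
            ConsistencyRecord(
                c, c.spread, sig_e, flag, "inconsistent" if flag else "none"
            )
        )
    return records


def outlier_scan(
    tree: ClusterTree, max_size: int = 2, min_height: float = 0.0
) -> list[Cluster]:
    """Small branches that merge into the rest at a high linkage distance.

    Walks merges from the root while their height is ≥ ``min_height``; every
    branch of ≤ ``max_size`` leaves hanging off such a merge is reported
    (e.g. a two-conformer branch at the topmost level of the dendrogram).
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    n = tree.n_leaves
    out: list[Cluster] = []

    def subtree_size(node: int) -> int:
        return 1 if node < n else tree.merges[node - n].count

    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        m = tree.merges[node - n]
        if m.height < min_height:
            continue
        for child in (m.left, m.right):
            if subtree_size(child) <= max_size:
                if child < n:
                    members = [child]
                else:
                    members = tree.leaves_of(child)
                out.append(
                    Cluster([tree.leaf_ids[i] for i in members], list(members))
                )
            else:
                stack.append(child)
    out.sort(key=lambda c: min(c.member_indices))
    return out


def screen_report(
    records: Sequence[ConsistencyRecord], path: str | Path | None = None
):
    """Tabular consistency report; optional TSV export."""
    import pandas as pd

    df = pd.DataFrame(
        [
            (
                k,
                len(r.cluster),
                r.cluster.representative_id,
                r.sigma_D,
                r.sigma_E,
                r.flagged,
                r.reason,
            )
            for k, r in enumerate(records)
        ],
        columns=[
            "cluster_id",
            "size",
            "representative_id",
            "sigma_D",
            "sigma_E",
            "flagged",
            "reason",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
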