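"""Nodal-degree hubs from PLV matrices.

A node's degree (strength) is the sum of its incident PLV edge weights.
Per subject, the top 5% of nodes by degree are its functional hubs; at
the group level each node's aggregated ranking is the fraction of
subjects whose hub set contains it, and the top 10% by that score are the
group's characteristic hubs.  Gyral-vs-sulcal hub participation is
compared between groups with contingency tables and a Mann-Whitney U
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .parcellation import RoiSet

__all__ = [
    "HubProfile",
    "GroupHubRanking",
    "nodal_degree",
    "top_hubs",
    "hub_profile",
    "aggregate_ranking",
    "hub_contingency",
    "mann_whitney_u",
]


@dataclass
class HubProfile:
    """One subject's nodal degrees and top-fraction hub set."""

    dnodal: np.ndarray
    top_set: frozenset
    gyral_count: int = 0
    sulcal_count: int = 0


@dataclass
class GroupHubRanking:
    """Per-node aggregate hub score and the group-level hub set."""

    scores: np.ndarray  # in [0, 1]
    hub_set: frozenset


def nodal_degree(plv: np.ndarray) -> np.ndarray:
    """Sum of incident edge weights per node, diagonal excluded.

    NaN rows (flagged-empty nodes) stay NaN and are skipped in the other
    nodes' sums.
    """
    plv = np.asarray(plv, dtype=float)
    valid = ~np.isnan(plv).all(axis=1)
    work = np.where(np.isnan(plv), 0.0, plv)
    deg = work.sum(axis=1) - np.diag(work)
    deg[~valid] = np.nan
    return deg


def top_hubs(dnodal: np.ndarray, fraction: float = 0.05) -> frozenset:
    """Indices of the floor(fraction * N) highest-degree nodes.

    For N = 64 and fraction 0.05 this is 3 hubs per subject.  Ties at the
    cutoff are broken by node index (stable sort); NaN nodes are never
    hubs.
    """
    dnodal = np.asarray(dnodal, dtype=float)
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    k = math.floor(fraction * dnodal.size)
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {dnodal.size} nodes selects no hub"
        )
    order = np.argsort(-dnodal, kind="stable")  # NaNs sort last
    return frozenset(order[:k].tolist())


def hub_profile(
    plv: np.ndarray, rois: Optional[RoiSet] = None, fraction: float = 0.05
) -> HubProfile:
    """Degree + hub set for one subject, with gyral/sulcal counts."""
    deg = nodal_degree(plv)
    top = top_hubs(deg, fraction)
    gyral = sulcal = 0
    if rois is not None:
        mask = rois.gyral_mask
        gyral = sum(1 for i in top if mask[i])
        sulcal = len(top) - gyral
    return HubProfile(
        dnodal=deg, top_set=top, gyral_count=gyral, sulcal_count=sulcal
    )


def aggregate_ranking(
    profiles: Sequence[HubProfile],
    fraction: float = 0.10,
    method: str = "membership",
) -> GroupHubRanking:
    """Group-level hub ranking across subjects.

    method "membership" (default): each node's score is the fraction of
    subjects whose top set contains it.  method "mean_rank": the mean
    percentile rank of the node's degree across subjects (an alternative
    reading of "aggregated ranking percentage"; the two orderings agree
    on strongly ranked nodes).  The group hub set is the top
    floor(fraction * N) nodes by score, ties broken by node index.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    n = profiles[0].dnodal.size
    if method == "membership":
        scores = np.zeros(n)
        for p in profiles:
            for i in p.top_set:
                scores[i] += 1.0
        scores /= len(profiles)
    elif method == "mean_rank":
        ranks = np.zeros(n)
        for p in profiles:
            d = np.where(np.isnan(p.dnodal), -np.inf, p.dnodal)
            ranks += (stats.rankdata(d) - 1) / (n - 1)
        scores = ranks / len(profiles)
    else:
        raise ValueError("method must be 'membership' or 'mean_rank'")
    k = math.floor(fraction * n)
    if k == 0:
        raise ValueError("fraction selects no group hub")
    order = np.argsort(-scores, kind="stable")
    return GroupHubRanking(scores=scores, hub_set=frozenset(order[:k].tolist()))


def hub_contingency(
    profiles_a: Sequence[HubProfile],
    profiles_b: Sequence[HubProfile],
    group_names: Tuple[str, str] = ("A", "B"),
) -> dict:
    """Contingency tables of per-subject gyral and sulcal hub counts.

    Returns {"gyral": table, "sulcal": table} where each table is a
    (2, k+1) array of subject counts with 0..k hubs of that fold class
    (k = hub-set size; 3 for the 5% rule at N = 64), rows in the order
    ``group_names``.  Rows sum to the group sizes.
    """
    k = max(
        len(p.top_set) for p in list(profiles_a) + list(profiles_b)
    )
    out = {}
    for kind in ("gyral", "sulcal"):
        table = np.zeros((2, k + 1), dtype=int)
        for row, profiles in enumerate((profiles_a, profiles_b)):
            for p in profiles:
                c = p.gyral_count if kind == "gyral" else p.sulcal_count
                table[row, c] += 1
        out[kind] = table
    out["group_names"] = group_names
    return out


def mann_whitney_u(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    alternative: str = "greater",
) -> Tuple[float, float]:
    """Mann-Whitney U with midranks, tie-corrected normal approximation
    and continuity correction.

    ``alternative="greater"`` tests whether sample a is stochastically
    larger.  If every value in both samples is identical the test is
    degenerate; U is the null mean and p = 1 (flagged with a warning).
    """
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn(
            "all values identical across both samples; degenerate test",
            RuntimeWarning,
            stacklevel=2,
        )
        return a.size * b.size / 2.0, 1.0
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)
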