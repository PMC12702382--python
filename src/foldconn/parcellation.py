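"""Curvature-based gyral/sulcal parcellation.

Each atlas region is split into a gyral part (vertex curvature r above a
threshold, convex crowns) and a sulcal part (r below), giving a node set
of 2 x n_regions ROIs.  Vertex signals are aggregated to one series per
ROI.  The curvature sign convention is gyri-positive; adapters for real
surface files must verify (and if needed flip) the sign before calling
into this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FoldClass",
    "UNASSIGNED",
    "SurfaceModel",
    "RoiNode",
    "RoiSet",
    "classify_vertices",
    "build_roi_set",
    "roi_timeseries",
]

#: Sentinel for vertices outside the atlas (medial wall, unlabeled).
UNASSIGNED = -1


class FoldClass(IntEnum):
    """Fold class of a vertex or ROI: sulcal valley or gyral crown."""

    SULCAL = 0
    GYRAL = 1


@dataclass
class SurfaceModel:
    """Cortical surface with per-vertex curvature, atlas labels and signals.

    Parameters
    ----------
    curvature : (n_vertices,) float array
        Dimensionless vertex curvature, gyri-positive convention.
    region_label : (n_vertices,) int array
        Atlas region id in ``1..n_regions``; 0 marks unlabeled vertices
        (medial wall), excluded from every ROI.
    vertex_signal : (n_vertices, n_time) float array, optional
        Per-vertex time series (e.g. surface-mapped BOLD).
    tr : float
        Sampling interval of ``vertex_signal`` in seconds.
    """

    curvature: np.ndarray
    region_label: np.ndarray
    vertex_signal: Optional[np.ndarray] = None
    tr: float = 0.392

    def __post_init__(self) -> None:
        self.curvature = np.asarray(self.curvature, dtype=float)
        self.region_label = np.asarray(self.region_label, dtype=int)
        if self.curvature.ndim != 1:
            raise ValueError("curvature must be one value per vertex")
        if self.region_label.shape != self.curvature.shape:
            raise ValueError(
                "region_label and curvature must have the same length"
            )
        if self.vertex_signal is not None:
            self.vertex_signal = np.asarray(self.vertex_signal, dtype=float)
            if self.vertex_signal.shape[0] != self.vertex_count:
                raise ValueError(
                    "vertex_signal first axis must match vertex_count"
                )

    @property
    def vertex_count(self) -> int:
        return self.curvature.shape[0]


@dataclass(frozen=True)
class RoiNode:
    """One node of the fold-stratified scheme: a (region, fold) part."""

    region_id: int
    fold_class: FoldClass
    hemisphere: str = "NA"  # {"L", "R", "NA"} — metadata only
    name: str = ""


@dataclass
class RoiSet:
    """Ordered fold-stratified node set with per-vertex assignment.

    Nodes are ordered by region id, gyral before sulcal, so node
    ``2*(region_id-1)`` is the gyral and ``2*(region_id-1)+1`` the sulcal
    part of each region.  Empty (region, fold) combinations are retained
    and flagged so matrices keep fixed dimension across subjects.
    """

    nodes: list
    vertex_assignment: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.vertex_assignment = np.asarray(self.vertex_assignment, dtype=int)
        seen = set()
        for node in self.nodes:
            key = (node.region_id, node.fold_class)
            if key in seen:
                raise ValueError(f"duplicate node {key}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def gyral_mask(self) -> np.ndarray:
        """Boolean mask over nodes, True where the node is gyral."""
        return np.array(
            [n.fold_class == FoldClass.GYRAL for n in self.nodes], dtype=bool
        )

    @property
    def vertex_counts(self) -> np.ndarray:
        """Number of vertices assigned to each node."""
        counts = np.zeros(self.n_nodes, dtype=int)
        assigned = self.vertex_assignment[self.vertex_assignment >= 0]
        np.add.at(counts, assigned, 1)
        return counts

    @property
    def empty_mask(self) -> np.ndarray:
        """True for nodes with no assigned vertex (flagged, not dropped)."""
        return self.vertex_counts == 0

    def node_index(self, region_id: int, fold_class: FoldClass) -> int:
        for i, node in enumerate(self.nodes):
            if node.region_id == region_id and node.fold_class == fold_class:
                return i
        raise KeyError((region_id, fold_class))

    @classmethod
    def canonical(
        cls,
        n_regions: int = 32,
        hemisphere_of=None,
    ) -> "RoiSet":
        """The standard 2*n_regions node set with no vertex assignment.

        ``hemisphere_of`` maps a region id to "L"/"R"; the default splits
        regions 1..n/2 left, rest right (metadata only — no operation
        depends on hemisphere).
        """
        if hemisphere_of is None:
            half = n_regions // 2
            hemisphere_of = lambda r: "L" if r <= half else "R"  # noqa: E731
        nodes = []
        for region in range(1, n_regions + 1):
            for fold in (FoldClass.GYRAL, FoldClass.SULCAL):
                nodes.append(
                    RoiNode(
                        region_id=region,
                        fold_class=fold,
                        hemisphere=hemisphere_of(region),
                        name=f"R{region:02d}_{fold.name[0]}",
                    )
                )
        return cls(nodes=nodes)


def classify_vertices(
    curvature: np.ndarray,
    threshold: float = 0.15,
    region_label: Optional[np.ndarray] = None,
    tie_rule: str = "sulcal",
) -> np.ndarray:
    """Classify vertices as gyral (r > threshold) or sulcal (r < threshold).

    Ties ``r == threshold`` go to the class named by ``tie_rule``
    ("sulcal" by default: the gyral rule is strict).  If ``region_label``
    is given, vertices labeled 0 are returned as :data:`UNASSIGNED`
    regardless of curvature.

    Returns an int array of :class:`FoldClass` values (or UNASSIGNED).
    """
    curvature = np.asarray(curvature, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    bad = np.flatnonzero(~np.isfinite(curvature))
    if bad.size:
        raise ValueError(
            f"non-finite curvature at vertex index {bad[0]} "
            f"({bad.size} offending vertices in total)"
        )
    if tie_rule not in ("sulcal", "gyral"):
        raise ValueError("tie_rule must be 'sulcal' or 'gyral'")

    if tie_rule == "sulcal":
        gyral = curvature > threshold
    else:
        gyral = curvature >= threshold
    out = np.where(gyral, int(FoldClass.GYRAL), int(FoldClass.SULCAL))
    if region_label is not None:
        out = np.where(np.asarray(region_label) == 0, UNASSIGNED, out)
    return out


def build_roi_set(
    surface: SurfaceModel,
    threshold: float = 0.15,
    tie_rule: str = "sulcal",
    n_regions: Optional[int] = None,
    hemisphere_of=None,
) -> RoiSet:
    """Split every atlas region at the curvature threshold into 2 ROIs.

    All ``2 * n_regions`` nodes are created in deterministic order
    (region id ascending, gyral before sulcal); combinations with no
    vertex are kept and flagged empty so downstream matrices have a fixed
    dimension.  ``n_regions`` defaults to the largest label present.
    """
    labels = surface.region_label
    labeled = labels > 0
    if not labeled.any():
        raise ValueError("surface has no labeled vertices")
    if n_regions is None:
        n_regions = int(labels.max())
    offending = np.unique(labels[(labels < 0) | (labels > n_regions)])
    if offending.size:
        raise ValueError(
            f"region labels outside atlas range 1..{n_regions}: "
            f"{offending.tolist()}"
        )

    roiset = RoiSet.canonical(n_regions=n_regions, hemisphere_of=hemisphere_of)
    fold = classify_vertices(
        surface.curvature, threshold, region_label=labels, tie_rule=tie_rule
    )
    assignment = np.full(surface.vertex_count, UNASSIGNED, dtype=int)
    gyral = fold == int(FoldClass.GYRAL)
    sulcal = fold == int(FoldClass.SULCAL)
    # node layout: gyral part of region r at 2(r-1), sulcal at 2(r-1)+1
    assignment[labeled & gyral] = 2 * (labels[labeled & gyral] - 1)
    assignment[labeled & sulcal] = 2 * (labels[labeled & sulcal] - 1) + 1
    roiset.vertex_assignment = assignment
    return roiset


def roi_timeseries(
    surface: SurfaceModel,
    rois: RoiSet,
    aggregation: str = "mean",
) -> np.ndarray:
    """Aggregate vertex signals into one series per ROI.

    Row ``i`` is the unweighted mean (or median) over vertices assigned
    to node ``i`` at each time point; empty nodes yield a NaN row,
    flagged for exclusion downstream rather than silently zero-filled.
    """
    if surface.vertex_signal is None:
        raise ValueError("surface has no vertex_signal")
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    if rois.empty_mask.all():
        raise ValueError("every ROI is empty; nothing to aggregate")

    n_time = surface.vertex_signal.shape[1]
    out = np.full((rois.n_nodes, n_time), np.nan)
    assignment = rois.vertex_assignment
    for i in range(rois.n_nodes):
        members = assignment == i
        if not members.any():
            continue
        block = surface.vertex_signal[members]
        out[i] = block.mean(axis=0) if aggregation == "mean" else np.median(
            block, axis=0
        )
    return out
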