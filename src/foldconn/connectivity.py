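"""Tract-count structural connectivity and gyral/sulcal edge classes.

The structural connectivity (SC) matrix entry for a pair of ROIs is the
number of tractography streamlines joining them divided by the
whole-brain streamline total, so all distinct-pair entries sum to at most
one.  Edges between two gyral nodes are GG, two sulcal nodes SS, mixed
pairs GS; class-averaged strengths and the GG/GS ratio summarize how
connectivity distributes over the folding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .parcellation import RoiSet, UNASSIGNED

__all__ = [
    "EdgeClass",
    "SCMatrix",
    "build_sc",
    "classify_edges",
    "class_mean_strength",
    "gg_gs_ratio",
]


class EdgeClass(IntEnum):
    GG = 0
    GS = 1
    SS = 2


@dataclass
class SCMatrix:
    """Symmetric nonnegative matrix of normalized streamline counts."""

    values: np.ndarray
    rois: RoiSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.rois.n_nodes
        if self.values.shape != (n, n):
            raise ValueError(f"SC matrix must be {n}x{n}")
        if (self.values < 0).any():
            raise ValueError("SC entries must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("SC matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def pair_sum(self) -> float:
        """Sum over distinct pairs (i<j); <= 1 by normalization."""
        return float(np.triu(self.values, k=1).sum())


def build_sc(
    endpoints: np.ndarray,
    rois: RoiSet,
    total_count: int,
) -> SCMatrix:
    """Normalized tract-count SC matrix from streamline endpoint ROIs.

    Parameters
    ----------
    endpoints : (n_streamlines, 2) int array
        ROI index of each streamline's two endpoints; ``UNASSIGNED`` (-1)
        marks an endpoint outside every ROI.  Streamlines with any
        unassigned endpoint contribute only to the denominator.
    total_count : int
        Whole-brain streamline total (the normalizing denominator); must
        be at least the number of listed streamlines.
    """
    endpoints = np.asarray(endpoints, dtype=int)
    if endpoints.ndim != 2 or endpoints.shape[1] != 2:
        raise ValueError("endpoints must be an (n, 2) array")
    if total_count <= 0:
        raise ValueError("total_count must be a positive integer")
    if total_count < endpoints.shape[0]:
        raise ValueError(
            "total_count must be >= the number of listed streamlines"
        )
    n = rois.n_nodes
    if ((endpoints >= n) | ((endpoints < 0) & (endpoints != UNASSIGNED))).any():
        raise ValueError("endpoint ROI index out of range")

    ok = (endpoints[:, 0] != UNASSIGNED) & (endpoints[:, 1] != UNASSIGNED)
    a, b = endpoints[ok, 0], endpoints[ok, 1]
    counts = np.zeros((n, n))
    np.add.at(counts, (np.minimum(a, b), np.maximum(a, b)), 1.0)
    off = np.triu(counts, k=1)
    counts = off + off.T + np.diag(np.diag(counts))
    return SCMatrix(values=counts / float(total_count), rois=rois)


def classify_edges(rois: RoiSet) -> np.ndarray:
    """Per-pair edge class matrix: GG, GS or SS (diagonal = -1).

    For g gyral and s sulcal nodes the distinct-pair counts satisfy
    |GG| = g(g-1)/2, |SS| = s(s-1)/2, |GS| = g*s.
    """
    gyral = rois.gyral_mask.astype(int)
    # gyral+gyral sums to 2 -> GG(0); mixed 1 -> GS(1); sulcal 0 -> SS(2)
    classes = 2 - (gyral[:, None] + gyral[None, :])
    np.fill_diagonal(classes, -1)
    return classes


def class_mean_strength(
    sc: SCMatrix,
    classes: np.ndarray,
    which: EdgeClass,
    include_zeros: bool = True,
    exclude_empty: bool = True,
) -> float:
    """Average SC strength over all distinct pairs of one edge class.

    Zero entries count toward the average by default (the class mean is
    over pairs, not over existing connections); pairs touching an empty
    fold node are excluded rather than imputed as zero.  The diagonal is
    never included.
    """
    which = EdgeClass(which)
    n = sc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    keep = classes[iu, ju] == int(which)
    if exclude_empty and sc.rois.vertex_assignment.size:
        empty = sc.rois.empty_mask
        keep &= ~empty[iu] & ~empty[ju]
    vals = sc.values[iu[keep], ju[keep]]
    if not include_zeros:
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(f"no usable pairs in class {which.name}")
    return float(vals.mean())


def gg_gs_ratio(sc: SCMatrix, classes: np.ndarray, **kwargs) -> float:
    """Ratio of mean gyri-to-gyri strength to mean gyri-to-sulci strength."""
    gg = class_mean_strength(sc, classes, EdgeClass.GG, **kwargs)
    gs = class_mean_strength(sc, classes, EdgeClass.GS, **kwargs)
    if gs == 0:
        raise ZeroDivisionError(
            "mean GS strength is zero; GG/GS ratio undefined"
        )
    return gg / gs
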