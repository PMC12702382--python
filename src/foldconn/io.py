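"""Plain-text readers/writers for the pipeline's small data formats.

All interchange is delimited text: a surface fixture table (vertex_id,
curvature, region_label, optional t0..tK signal columns), a streamline
endpoint list (streamline_id, node_a, node_b with -1 = unassigned),
square matrices with a node-name header row (SC, PLV, t matrices), and
the cohort manifest.  Adapters for GIFTI/NIfTI real-data inputs can be
layered on top (nibabel) but are not required for the synthetic path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .parcellation import RoiSet, SurfaceModel

__all__ = [
    "read_surface_table",
    "write_surface_table",
    "read_endpoints",
    "write_endpoints",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
]


def write_surface_table(path, surface: SurfaceModel) -> None:
    data = {
        "vertex_id": np.arange(surface.vertex_count),
        "curvature": surface.curvature,
        "region_label": surface.region_label,
    }
    if surface.vertex_signal is not None:
        for t in range(surface.vertex_signal.shape[1]):
            data[f"t{t}"] = surface.vertex_signal[:, t]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_surface_table(path, tr: float = 0.392) -> SurfaceModel:
    df = pd.read_csv(path, sep="\t")
    signal_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    signal_cols.sort(key=lambda c: int(c[1:]))
    signal = df[signal_cols].to_numpy(float) if signal_cols else None
    return SurfaceModel(
        curvature=df["curvature"].to_numpy(float),
        region_label=df["region_label"].to_numpy(int),
        vertex_signal=signal,
        tr=tr,
    )


def write_endpoints(path, endpoints: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "streamline_id": np.arange(len(endpoints)),
            "node_a": endpoints[:, 0],
            "node_b": endpoints[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_endpoints(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[["node_a", "node_b"]].to_numpy(int)


def write_matrix(path, values: np.ndarray, rois: Optional[RoiSet] = None) -> None:
    """Square matrix as TSV with a node-name header row."""
    values = np.asarray(values)
    names = (
        [n.name for n in rois.nodes]
        if rois is not None
        else [f"n{i}" for i in range(values.shape[0])]
    )
    pd.DataFrame(values, columns=names).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> Tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), list(df.columns)


def write_cohort(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
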