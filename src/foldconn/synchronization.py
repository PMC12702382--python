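"""Phase-synchronization measures for ROI BOLD signals.

ROI series are band-pass filtered (Butterworth, zero-phase), reduced to
instantaneous phases with the Hilbert transform, and trimmed at both ends
to discard filter/transform edge effects.  Synchrony is then measured two
ways: the Kuramoto order parameter

    r(t) = | (1/M) sum_j exp(i phi_j(t)) |            (over a node subset)

whose time average is the "mean synchronization" of the subset, and the
phase-locking value

    PLV(a, b) = | (1/T) sum_t exp(i (phi_a(t) - phi_b(t))) |

a pairwise synchrony matrix independent of signal amplitude.  Both lie in
[0, 1]: 1 means full coherence, values near 1/sqrt(T or M) indicate
incoherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .parcellation import RoiSet

__all__ = [
    "PhaseBundle",
    "KopSeries",
    "bandpass",
    "instantaneous_phase",
    "trim",
    "phase_pipeline",
    "kop",
    "plv",
]


@dataclass
class PhaseBundle:
    """Per-subject instantaneous phases after filtering and trimming.

    ``phases`` is (n_rois, n_time) in radians wrapped to (-pi, pi]; NaN
    rows mark flagged-empty ROIs and are excluded from KOP subsets and
    the PLV matrix rather than propagated silently.
    """

    phases: np.ndarray
    tr: float = 0.392
    trim_applied: int = 0
    band: Tuple[float, float] = (0.02, 0.10)
    rois: Optional[RoiSet] = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2 or self.phases.shape[1] == 0:
            raise ValueError("phases must be a nonempty (n_rois, n_time) array")

    @property
    def n_rois(self) -> int:
        return self.phases.shape[0]

    @property
    def n_time(self) -> int:
        return self.phases.shape[1]

    @property
    def valid_rows(self) -> np.ndarray:
        return ~np.isnan(self.phases).any(axis=1)


@dataclass
class KopSeries:
    """Kuramoto order parameter over time for one node subset."""

    values: np.ndarray
    subset: str
    mean_sync: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean_sync = float(self.values.mean())


def bandpass(
    series: np.ndarray,
    tr: float = 0.392,
    low: float = 0.02,
    high: float = 0.10,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass per ROI row.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    pass band carries no phase distortion — essential before Hilbert
    phase extraction.  Output length equals input length.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist = {nyquist:.4f} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr,
                        output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def instantaneous_phase(filtered: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal per row, wrapped to (-pi, pi].

    Rows that are identically zero have no defined phase; they come back
    as NaN rows with a warning (flagged, not silently propagated).
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    phases = np.angle(signal.hilbert(filtered, axis=-1))
    phases[phases == -np.pi] = np.pi
    dead = ~filtered.any(axis=-1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-zero row(s): phases set to NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        phases[dead] = np.nan
    return phases


def trim(
    phases: np.ndarray,
    n_trim: int = 50,
    tr: float = 0.392,
    band: Tuple[float, float] = (0.02, 0.10),
    rois: Optional[RoiSet] = None,
) -> PhaseBundle:
    """Drop ``n_trim`` samples from each end (default 50 TR ~ 20 s)."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    n_time = phases.shape[1]
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_time <= 2 * n_trim:
        raise ValueError(
            f"series of length {n_time} too short to trim {n_trim} "
            "samples from each end"
        )
    trimmed = phases[:, n_trim:n_time - n_trim] if n_trim else phases
    return PhaseBundle(
        phases=trimmed, tr=tr, trim_applied=n_trim, band=band, rois=rois
    )


def phase_pipeline(
    series: np.ndarray,
    tr: float = 0.392,
    low: float = 0.02,
    high: float = 0.10,
    order: int = 2,
    n_trim: int = 50,
    rois: Optional[RoiSet] = None,
) -> PhaseBundle:
    """Band-pass -> Hilbert phase -> trim, with the study defaults.

    NaN rows in the input (flagged-empty ROIs) are carried through as NaN
    phase rows.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    nan_rows = np.isnan(series).any(axis=1)
    work = np.where(nan_rows[:, None], 0.0, series)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phases = instantaneous_phase(bandpass(work, tr, low, high, order))
    phases[nan_rows] = np.nan
    return trim(phases, n_trim=n_trim, tr=tr, band=(low, high), rois=rois)


_PRESETS = ("global", "gyri", "sulci")


def kop(bundle: PhaseBundle, subset="global") -> KopSeries:
    """Kuramoto order parameter series over a node subset.

    ``subset`` is either a preset ("global", "gyri", "sulci" — the last
    two need ``bundle.rois``) or an explicit sequence of node indices.
    NaN (flagged-empty) rows are excluded from presets and rejected in
    explicit subsets.
    """
    valid = bundle.valid_rows
    if isinstance(subset, str):
        name = subset.lower()
        if name not in _PRESETS:
            raise ValueError(f"unknown subset preset {subset!r}")
        if name == "global":
            mask = valid.copy()
        else:
            if bundle.rois is None:
                raise ValueError(f"subset {name!r} requires bundle.rois")
            mask = bundle.rois.gyral_mask if name == "gyri" else ~bundle.rois.gyral_mask
            mask = mask & valid
        idx = np.flatnonzero(mask)
        label = name.upper()
    else:
        idx = np.asarray(list(subset), dtype=int)
        label = "CUSTOM"
        if idx.size and not valid[idx].all():
            raise ValueError("subset contains flagged-empty (NaN) nodes")
    if idx.size == 0:
        raise ValueError("empty node subset")
    resultant = np.exp(1j * bundle.phases[idx]).mean(axis=0)
    return KopSeries(values=np.abs(resultant), subset=label)


def plv(bundle: PhaseBundle) -> np.ndarray:
    """Phase-locking value matrix over all node pairs.

    Returns an (n_rois, n_rois) symmetric matrix in [0, 1] with unit
    diagonal; rows/columns of flagged-empty nodes are NaN.
    """
    if bundle.n_time < 2:
        raise ValueError("PLV needs at least 2 time points")
    valid = bundle.valid_rows
    phasors = np.exp(1j * bundle.phases[valid])
    sub = np.abs(phasors @ phasors.conj().T) / bundle.n_time
    np.fill_diagonal(sub, 1.0)
    out = np.full((bundle.n_rois, bundle.n_rois), np.nan)
    idx = np.flatnonzero(valid)
    out[np.ix_(idx, idx)] = np.clip(sub, 0.0, 1.0)
    return out
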