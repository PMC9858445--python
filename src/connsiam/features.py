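"""Dynamic functional-connectivity features from ROI BOLD time series.

The time series is divided into overlapping sliding windows of ``M``
timepoints (stride ``s``); each window yields a region-by-region Pearson
correlation matrix (a sub-network of the dynamic FCN).  The elementwise mean
of the window matrices is the subject's connectivity estimate, and its upper
triangle (row-major, i < j) is the feature vector fed to the similarity model
-- length R(R-1)/2, i.e. 6670 for the 116-region AAL parcellation.

Neither the window length nor the stride is a property of the method itself;
the defaults (M=30 timepoints, stride 1) follow common sliding-window
practice and are configurable everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ROITimeSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: window length (timepoints) and stride."""

    window_length: int = 30
    stride: int = 1

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class SubFCN:
    """One window's functional-connectivity matrix; ``k`` is 1-based."""

    k: int
    fc: np.ndarray


@dataclass(frozen=True)
class DynamicFCN:
    windows: tuple[SubFCN, ...]

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def enumerate_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based window intervals; trailing partial windows dropped.

    K = floor((T - M) / s) + 1 windows, each of length exactly M.
    """
    M, s = spec.window_length, spec.stride
    if M > n_timepoints:
        raise ValueError(
            f"window longer than series (M={M}, T={n_timepoints})"
        )
    n_windows = (n_timepoints - M) // s + 1
    return [(k * s, k * s + M) for k in range(n_windows)]


def _window_correlation(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of an M x R window.

    Zero-variance regions get correlation 0 with every other region (a
    constant signal carries no correlation evidence); diagonal stays 1.
    """
    centered = segment - segment.mean(axis=0)
    cross = centered.T @ centered
    norms = np.sqrt(np.diag(cross))
    degenerate = norms == 0.0
    if degenerate.any():
        logger.warning(
            "zero-variance region(s) in window: %s", np.nonzero(degenerate)[0].tolist()
        )
    safe = np.where(degenerate, 1.0, norms)
    corr = cross / np.outer(safe, safe)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def pearson_window(
    ts: ROITimeSeries, window: tuple[int, int], i: int, j: int
) -> float:
    """Pearson correlation of regions i and j over one window."""
    start, end = window
    if not (0 <= start < end <= ts.n_timepoints):
        raise ValueError(f"window {window} outside series of length {ts.n_timepoints}")
    segment = ts.data[start:end, :]
    return float(_window_correlation(segment)[i, j])


def build_dfcn(ts: ROITimeSeries, spec: WindowSpec) -> DynamicFCN:
    """Construct the dynamic FCN: one correlation matrix per sliding window."""
    intervals = enumerate_windows(ts.n_timepoints, spec)
    windows = tuple(
        SubFCN(k=k + 1, fc=_window_correlation(ts.data[start:end, :]))
        for k, (start, end) in enumerate(intervals)
    )
    return DynamicFCN(windows=windows)


def mean_fcn(dfcn: DynamicFCN) -> np.ndarray:
    """Elementwise mean over the window matrices."""
    if dfcn.n_windows == 0:
        raise ValueError("empty dynamic FCN")
    return np.mean([w.fc for w in dfcn.windows], axis=0)


def vectorize_upper(mat: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Upper triangle (i < j, row-major) of a symmetric matrix as a vector.

    Length is R(R-1)/2; the fixed element order makes feature files and
    model inputs comparable across runs.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu].copy()


def devectorize(values: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` with a unit diagonal."""
    values = np.asarray(values, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if values.shape != (expected,):
        raise ValueError(f"expected {expected} values for R={n_regions}")
    mat = np.eye(n_regions)
    iu = np.triu_indices(n_regions, k=1)
    mat[iu] = values
    mat[(iu[1], iu[0])] = values
    return mat


def subject_features(
    ts: ROITimeSeries, spec: WindowSpec, *, fisher_z: bool = False
) -> np.ndarray:
    """Full per-subject pipeline: windows -> mean FCN -> upper-triangle vector.

    ``fisher_z`` applies arctanh to the (clipped) mean correlations; off by
    default since the similarity model consumes raw correlations.
    """
    vec = vectorize_upper(mean_fcn(build_dfcn(ts, spec)))
    if fisher_z:
        vec = np.arctanh(np.clip(vec, -1 + 1e-7, 1 - 1e-7))
    return vec


def cohort_features(
    cohort: list[ROITimeSeries], spec: WindowSpec, *, fisher_z: bool = False
) -> pd.DataFrame:
    """Feature table for a cohort: subject_id, site_id, label, f1..fP."""
    if not cohort:
        raise ValueError("empty cohort")
    n_regions = cohort[0].n_regions
    n_features = n_regions * (n_regions - 1) // 2
    rows = []
    for ts in cohort:
        if ts.n_regions != n_regions:
            raise ValueError(
                f"subject {ts.subject_id}: {ts.n_regions} regions, expected {n_regions}"
            )
        rows.append(subject_features(ts, spec, fisher_z=fisher_z))
    table = pd.DataFrame(np.asarray(rows), columns=[f"f{i+1}" for i in range(n_features)])
    table.insert(0, "label", [ts.label for ts in cohort])
    table.insert(0, "site_id", [ts.site_id for ts in cohort])
    table.insert(0, "subject_id", [ts.subject_id for ts in cohort])
    return table
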