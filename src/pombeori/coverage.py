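"""Transcription-coverage and DNA copy-number features.

``l_ntx`` is the third origin determinant: the length of the transcription-
poor region, measured as the longest contiguous run of positions whose
per-base RNA-seq depth is <= 1 inside the analysis window (runs truncate at
window edges). The copy-number path reproduces the replication-initiation
sanity check: per-100 bp sample/reference depth ratios, LOESS-smoothed
(span 0.005, local quadratic, tricube weights) and scaled so the 25th
percentile equals 1.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "l_ntx",
    "copy_number_ratio",
    "loess_smooth",
    "scale_quartile",
    "longest_run",
]

L_NTX_MAX_COUNT = 1
LOESS_SPAN = 0.005


def longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def l_ntx(
    coverage: np.ndarray,
    window_interval: GenomicInterval,
    max_count: float = L_NTX_MAX_COUNT,
    mode: str = "run",
) -> int:
    """Transcription-poor length in the window.

    ``mode='run'`` (default): longest contiguous run of positions with depth
    <= ``max_count``; ``mode='total'``: total number of qualifying positions.
    """
    window = np.asarray(coverage)[window_interval.start : window_interval.end]
    quiet = window <= max_count
    if mode == "run":
        return longest_run(quiet)
    if mode == "total":
        return int(np.count_nonzero(quiet))
    raise ValueError(f"unknown mode {mode!r}")


def copy_number_ratio(
    sample_bins: np.ndarray | Mapping[str, np.ndarray],
    reference_bins: np.ndarray | Mapping[str, np.ndarray],
) -> np.ndarray | dict[str, np.ndarray]:
    """Depth-normalized per-bin sample/reference ratio; zero-reference bins NaN."""
    if isinstance(sample_bins, Mapping):
        if set(sample_bins) != set(reference_bins):
            raise ValueError("sample and reference cover different chromosomes")
        s_total = sum(float(np.sum(a)) for a in sample_bins.values())
        r_total = sum(float(np.sum(a)) for a in reference_bins.values())
        out = {}
        for chrom in sample_bins:
            out[chrom] = _ratio(
                np.asarray(sample_bins[chrom], float),
                np.asarray(reference_bins[chrom], float),
                s_total, r_total,
            )
        return out
    s = np.asarray(sample_bins, dtype=float)
    r = np.asarray(reference_bins, dtype=float)
    if s.shape != r.shape:
        raise ValueError("mismatched bin grids")
    return _ratio(s, r, float(s.sum()), float(r.sum()))


def _ratio(s: np.ndarray, r: np.ndarray, s_total: float, r_total: float) -> np.ndarray:
    if s_total <= 0 or r_total <= 0:
        raise ValueError("zero total counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s / s_total) / (r / r_total)
    ratio[r == 0] = np.nan
    return ratio


def loess_smooth(
    values: np.ndarray,
    positions: np.ndarray | None = None,
    span: float = LOESS_SPAN,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    The neighbourhood of each point is the ``ceil(span * n)`` nearest points;
    since genomic bins are sorted and (near-)uniform, neighbourhoods are the
    contiguous windows minimizing the span distance. NaN inputs are ignored
    for fitting and smoothed values are returned at every input position.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if positions is None:
        positions = np.arange(n, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must align")
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValueError(f"span {span} x n {n} gives {k} < 3 points per fit")
    k = max(k, degree + 1)

    order = np.argsort(positions, kind="stable")
    x = positions[order]
    y = values[order]
    finite = np.isfinite(y)
    xf, yf = x[finite], y[finite]
    m = xf.size
    if m < k:
        raise ValueError("not enough finite values for the requested span")

    # contiguous k-window per evaluation point, chosen to minimize max distance
    left = np.searchsorted(xf, x) - k // 2
    left = np.clip(left, 0, m - k)
    # slide each window to the true distance-minimizing offset
    for _ in range(2):
        can_right = left + k < m
        move_right = can_right & (
            np.abs(xf[np.minimum(left + k, m - 1)] - x)
            < np.abs(xf[left] - x)
        )
        left = np.where(move_right, left + 1, left)
        can_left = left > 0
        move_left = can_left & (
            np.abs(xf[left - 1] - x) < np.abs(xf[np.minimum(left + k - 1, m - 1)] - x)
        )
        left = np.where(move_left, left - 1, left)

    idx = left[:, None] + np.arange(k)[None, :]
    xw = xf[idx]
    yw = yf[idx]
    d = np.abs(xw - x[:, None])
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    w = (1 - (d / dmax) ** 3) ** 3
    w = np.maximum(w, 1e-12)

    # weighted least squares, design centered at the evaluation point
    t = xw - x[:, None]
    scale = np.maximum(dmax[:, 0], 1.0)
    t = t / scale[:, None]
    cols = [np.ones_like(t)] + [t ** p for p in range(1, degree + 1)]
    X = np.stack(cols, axis=2)  # (n, k, degree+1)
    WX = X * w[:, :, None]
    XtWX = np.einsum("nkp,nkq->npq", WX, X)
    XtWy = np.einsum("nkp,nk->np", WX, yw)
    # intercept at t=0 is the smoothed value
    beta = np.linalg.solve(
        XtWX + 1e-12 * np.eye(degree + 1)[None, :, :], XtWy[:, :, None]
    )[:, 0, 0]

    out = np.empty(n)
    out[order] = beta
    return out


def scale_quartile(values: np.ndarray) -> np.ndarray:
    """Scale so the 25th percentile (linear-interpolation quantile) equals 1."""
    values = np.asarray(values, dtype=float)
    q25 = np.nanpercentile(values, 25)
    if q25 <= 0:
        raise ValueError("25th percentile must be positive to scale")
    return values / q25
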