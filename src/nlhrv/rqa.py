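"""Recurrence plots with a fixed amount of neighbors (FAN) and DET / LAM.

Under the FAN criterion every column i of the recurrence matrix marks the k
nearest phase-space neighbors of point x_i (self included), with
k = round(density * N'); the per-column tolerance eps_i adapts to local
point density, the matrix has exactly the requested recurrence density and
is in general asymmetric.  Determinism (DET) is the fraction of recurrence
points on diagonal lines of length >= l_min, laminarity (LAM) the fraction
on vertical lines of length >= v_min; both are computed from run-length
histograms of the binary matrix.  Diagonals within a Theiler window of the
line of identity are excluded from DET so self-recurrence does not count as
determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddedSeries

__all__ = [
    "RecurrenceMatrix",
    "LineHistograms",
    "fan_recurrence",
    "line_histograms",
    "determinism",
    "laminarity",
    "rqa_measures",
    "plot_recurrence",
]


@dataclass
class RecurrenceMatrix:
    R: np.ndarray            # (N', N') boolean, column i = neighbors of x_i
    density: float
    k: int
    theiler_window: int = 1
    norm: str = "fan"


@dataclass
class LineHistograms:
    """Run-length histograms; index l holds the count of lines of length l."""

    diag: np.ndarray
    vert: np.ndarray


def fan_recurrence(
    emb: EmbeddedSeries,
    density: float = 0.07,
    theiler_window: int = 1,
) -> RecurrenceMatrix:
    """FAN recurrence matrix at the given target density.

    For each column i the k = round(density * N') points nearest to x_i in
    Euclidean distance (the point itself always among them) are marked
    recurrent; ties at the k-th distance are broken toward the smaller
    index, which makes the construction fully deterministic.
    """
    X = emb.vectors
    n = X.shape[0]
    k = int(round(density * n))
    if k < 2:
        raise ValueError(
            f"series too short for density {density}: k={k} neighbors per column"
        )
    d = cdist(X, X)
    # fast path: unordered k smallest per column; exact unless the k-th
    # distance is tied, in which case a stable sort of that column applies
    # the smaller-index break
    part = np.argpartition(d, k - 1, axis=0)[:k]
    cols = np.arange(n)
    kth = d[part, cols].max(axis=0)
    tied = (d == kth[None, :]).sum(axis=0) > 1
    R = np.zeros((n, n), dtype=bool)
    R[part, cols[None, :]] = True
    for i in np.flatnonzero(tied):
        R[:, i] = False
        R[np.argsort(d[:, i], kind="stable")[:k], i] = True
    return RecurrenceMatrix(R=R, density=density, k=k, theiler_window=theiler_window)


def _run_length_hist(flat: np.ndarray, min_size: int) -> np.ndarray:
    """Histogram of runs of True in a 1-D array (separators must be False)."""
    a = np.empty(flat.size + 2, dtype=np.int8)
    a[0] = a[-1] = 0
    a[1:-1] = flat
    d = np.diff(a)
    lengths = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return np.bincount(lengths, minlength=min_size)


def line_histograms(mat: RecurrenceMatrix) -> LineHistograms:
    """Diagonal and vertical run-length histograms of a recurrence matrix.

    Diagonals with |i - j| < theiler_window are excluded (the line of
    identity and its immediate neighborhood); verticals are counted over the
    full matrix, LOI included, which is the standard convention.
    """
    R = mat.R
    n = R.shape[0]
    w = mat.theiler_window
    # diagonals, both triangles, outside the Theiler band
    pieces = []
    for off in range(w, n):
        pieces.append(R.diagonal(off))
        pieces.append(np.zeros(1, dtype=bool))
        if off > 0:
            pieces.append(R.diagonal(-off))
            pieces.append(np.zeros(1, dtype=bool))
    diag_flat = np.concatenate(pieces) if pieces else np.zeros(0, dtype=bool)
    diag_hist = _run_length_hist(diag_flat, min_size=2)
    # verticals: flatten column-major with a zero separator row
    padded = np.zeros((n + 1, n), dtype=bool)
    padded[:n] = R
    vert_hist = _run_length_hist(padded.T.ravel(), min_size=2)
    return LineHistograms(diag=diag_hist, vert=vert_hist)


def _line_fraction(hist: np.ndarray, min_len: int) -> float:
    lengths = np.arange(hist.size)
    weighted = lengths * hist
    total = weighted.sum()
    if total == 0:
        return np.nan
    return float(weighted[min_len:].sum() / total)


def determinism(hist: LineHistograms, l_min: int = 2) -> float:
    """DET: fraction of diagonal recurrence points in lines of length >= l_min.

    Undefined (NaN) when the diagonal histogram is empty.
    """
    return _line_fraction(hist.diag, l_min)


def laminarity(hist: LineHistograms, v_min: int = 2) -> float:
    """LAM: fraction of vertical recurrence points in lines of length >= v_min."""
    return _line_fraction(hist.vert, v_min)


def rqa_measures(
    emb: EmbeddedSeries,
    density: float = 0.07,
    l_min: int = 2,
    v_min: int = 2,
    theiler_window: int = 1,
) -> Tuple[float, float]:
    """(DET, LAM) of an embedded series via a FAN recurrence plot."""
    mat = fan_recurrence(emb, density=density, theiler_window=theiler_window)
    hist = line_histograms(mat)
    return determinism(hist, l_min), laminarity(hist, v_min)


def plot_recurrence(mat: RecurrenceMatrix, ax=None, **imshow_kwargs):
    """Render a recurrence plot (black = recurrence, origin lower-left)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    kwargs = {"cmap": "Greys", "origin": "lower", "interpolation": "none"}
    kwargs.update(imshow_kwargs)
    ax.imshow(mat.R.astype(float), **kwargs)
    ax.set_xlabel("beat index $j$")
    ax.set_ylabel("beat index $i$")
    return ax
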