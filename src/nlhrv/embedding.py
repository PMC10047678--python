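"""Delay-coordinate embedding and parameter selection (AMI, FNN).

The embedding delay tau is the first local minimum of the average mutual
information (AMI) between the series and its lagged copy; the embedding
dimension m is the smallest dimension at which the Kennel false-nearest-
neighbor (FNN) fraction drops to (approximately) zero.  AMI is estimated
from a 2-D histogram with equiprobable marginal bins, which is deterministic
and robust at the few-hundred-beat lengths typical of short-term HRV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "EmbeddedSeries",
    "mutual_information",
    "ami_curve",
    "select_tau",
    "fnn_curve",
    "select_m",
    "embed",
    "select_embedding",
]


@dataclass
class EmbeddingParams:
    m: int
    tau: int
    ami: Optional[np.ndarray] = None   # AMI at lags 1..max_lag (bits)
    fnn: Optional[np.ndarray] = None   # FNN fraction at m = 1..max_m

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be positive integers")


@dataclass
class EmbeddedSeries:
    vectors: np.ndarray  # (N', m)
    m: int
    tau: int
    source: str = ""

    @property
    def n_points(self) -> int:
        return int(self.vectors.shape[0])


def _equiprobable_edges(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return np.unique(edges)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: Optional[int] = None) -> float:
    """Mutual information in bits from an equiprobable-bin 2-D histogram."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if bins is None:
        bins = max(2, int(np.ceil(x.size ** (1.0 / 3.0))))
    ex = _equiprobable_edges(x, bins)
    ey = _equiprobable_edges(y, bins)
    if ex.size < 3 or ey.size < 3:
        return 0.0  # (near-)constant marginal: degenerate
    joint, _, _ = np.histogram2d(x, y, bins=(ex, ey))
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def ami_curve(x: np.ndarray, max_lag: int = 50, bins: Optional[int] = None) -> np.ndarray:
    """Average mutual information at lags 1..max_lag (bits).

    A constant series yields an all-zero curve (flagged with a warning).
    """
    x = np.asarray(x, float)
    if x.size < 4 * max_lag:
        max_lag = max(1, x.size // 4)
    if np.ptp(x) == 0:
        warnings.warn("constant series: AMI curve degenerate (all zero)")
        return np.zeros(max_lag)
    return np.array(
        [mutual_information(x[:-lag], x[lag:], bins=bins) for lag in range(1, max_lag + 1)]
    )


def select_tau(ami: np.ndarray, min_rise: float = 0.05, lookahead: int = 5) -> int:
    """Smallest lag that is a significant local minimum of the AMI curve.

    Histogram AMI estimates wobble by a few percent, so a strict local
    minimum is accepted only if the curve rises above it by more than
    ``min_rise`` times the curve's range within the next ``lookahead``
    lags; spurious one-sample dips on a monotone decay are thereby
    ignored.  Falls back to tau = 1 with a warning when no such minimum
    exists in the scanned range (e.g., strongly chaotic maps whose AMI
    decays monotonically).
    """
    ami = np.asarray(ami, float)
    if ami.size == 0:
        raise ValueError("empty AMI curve")
    rng_ = float(ami.max() - ami.min())
    tol = min_rise * rng_ if rng_ > 0 else 0.0
    for i in range(1, ami.size - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            ahead = ami[i + 1: i + 1 + lookahead]
            if ahead.size and float(ahead.max()) - ami[i] > tol:
                return i + 1  # lags are 1-based
    warnings.warn("no significant local minimum in AMI scan range; falling back to tau=1")
    return 1


def embed(x: np.ndarray, m: int, tau: int, source: str = "") -> EmbeddedSeries:
    """Delay-coordinate vectors (x_i, x_{i+tau}, ..., x_{i+(m-1)tau}).

    N' = N - (m-1)*tau vectors, values kept in original units.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be positive integers")
    n_prime = x.size - (m - 1) * tau
    if n_prime < 2:
        raise ValueError(
            f"series too short to embed: need > {(m - 1) * tau + 1} points, have {x.size}"
        )
    idx = np.arange(n_prime)[:, None] + tau * np.arange(m)[None, :]
    return EmbeddedSeries(x[idx], m=m, tau=tau, source=source)


def fnn_curve(
    x: np.ndarray,
    tau: int,
    max_m: int = 10,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
) -> np.ndarray:
    """Kennel false-nearest-neighbor fraction for m = 1..max_m.

    A neighbor pair at dimension m is "false" when the extra coordinate at
    dimension m+1 blows the distance up by more than ``r_tol`` relative to
    the m-dimensional distance, or beyond ``a_tol`` times the series spread.
    """
    x = np.asarray(x, float)
    sigma = np.std(x)
    if sigma == 0:
        warnings.warn("constant series: FNN degenerate")
        return np.zeros(max_m)
    fractions = np.full(max_m, np.nan)
    for m in range(1, max_m + 1):
        n_prime = x.size - m * tau  # points that also have an (m+1)-th coordinate
        if n_prime < 10:
            warnings.warn(f"FNN scan truncated at m={m - 1}: too few points")
            fractions = fractions[: m - 1]
            break
        emb = embed(x[: x.size - tau], m, tau).vectors[:n_prime]
        extra = x[m * tau:][:n_prime]
        tree = cKDTree(emb)
        dist, nn = tree.query(emb, k=2)
        d_m = dist[:, 1]
        j = nn[:, 1]
        valid = d_m > 0
        d_extra = np.abs(extra - extra[j])
        false = np.zeros(n_prime, dtype=bool)
        false[valid] = (d_extra[valid] / d_m[valid] > r_tol) | (
            np.sqrt(d_m[valid] ** 2 + d_extra[valid] ** 2) / sigma > a_tol
        )
        fractions[m - 1] = false[valid].mean() if valid.any() else 0.0
    return fractions


def select_m(fnn: np.ndarray, zero_tol: float = 0.01) -> int:
    """Smallest m whose FNN fraction is <= zero_tol; fallback: last scanned m."""
    fnn = np.asarray(fnn, float)
    if fnn.size == 0:
        raise ValueError("empty FNN curve")
    below = np.flatnonzero(fnn <= zero_tol)
    if below.size:
        return int(below[0]) + 1
    warnings.warn("FNN fraction never reached zero tolerance; using max scanned m")
    return int(fnn.size)


def select_embedding(
    x: np.ndarray,
    max_lag: int = 50,
    max_m: int = 10,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
    zero_tol: float = 0.01,
) -> EmbeddingParams:
    """Select (m, tau) from the data: AMI first minimum, then FNN."""
    ami = ami_curve(x, max_lag=max_lag)
    tau = select_tau(ami)
    fnn = fnn_curve(x, tau, max_m=max_m, r_tol=r_tol, a_tol=a_tol)
    m = select_m(fnn, zero_tol=zero_tol)
    return EmbeddingParams(m=m, tau=tau, ami=ami, fnn=fnn)
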