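"""Reading, ectopy correction and record-level quality gating of RR series.

Beat-to-beat (RR) interval series from short ECG recordings contain ectopic
beats and detection artifacts that corrupt variability statistics.  This
module reads plain-text / CSV interval files, replaces outlying beats with an
adaptive running estimate (so the output is an NN -- "normal-to-normal" --
series), and applies the record-level exclusion gates used in short-term HRV
studies: minimum recording duration and a cap on the fraction of replaced
beats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "RecordMetadata",
    "GateDecision",
    "read_rr",
    "write_rr",
    "adaptive_ectopic_filter",
    "exclusion_gate",
    "read_metadata",
    "screening_summary",
]

LABEL_NORMAL = "N"
LABEL_REPLACED = "R"


@dataclass
class RRSeries:
    """A beat-to-beat interval series in milliseconds.

    Attributes
    ----------
    intervals : ndarray of float
        RR/NN intervals in milliseconds, strictly positive.
    beat_labels : ndarray of str
        Per-interval label, ``"N"`` (normal) or ``"R"`` (replaced).
    record_id : str
        Identifier of the recording.
    moment : str or None
        Measurement moment, ``"pre"`` or ``"post"`` where applicable.
    """

    intervals: np.ndarray
    beat_labels: np.ndarray = None  # type: ignore[assignment]
    record_id: str = ""
    moment: Optional[str] = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size == 0:
            raise ValueError("no beats")
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("intervals must be finite")
        if np.any(self.intervals <= 0):
            bad = int(np.flatnonzero(self.intervals <= 0)[0])
            raise ValueError(f"non-positive interval at beat {bad + 1}")
        if self.beat_labels is None:
            self.beat_labels = np.full(self.intervals.size, LABEL_NORMAL, dtype="<U1")
        else:
            self.beat_labels = np.asarray(self.beat_labels, dtype="<U1")
            if self.beat_labels.shape != self.intervals.shape:
                raise ValueError("beat_labels length must match intervals")
        if self.moment is not None and self.moment not in ("pre", "post"):
            raise ValueError("moment must be 'pre' or 'post'")

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def total_duration(self) -> float:
        """Total recording time in seconds (sum of intervals)."""
        return float(self.intervals.sum() / 1000.0)

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds (time of each beat's end)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def replaced_fraction(self) -> float:
        return float(np.mean(self.beat_labels == LABEL_REPLACED))

    def copy(self) -> "RRSeries":
        return RRSeries(
            intervals=self.intervals.copy(),
            beat_labels=self.beat_labels.copy(),
            record_id=self.record_id,
            moment=self.moment,
        )


@dataclass
class RecordMetadata:
    record_id: str
    prior_mi: bool
    sex: Literal["female", "male"]
    age: float


@dataclass
class GateDecision:
    included: bool
    reason: Optional[str] = None  # "short" | "replacement"

    def __bool__(self) -> bool:
        return self.included


def read_rr(
    path: Union[str, Path, io.TextIOBase],
    dialect: str = "plain-ms",
    record_id: Optional[str] = None,
    moment: Optional[str] = None,
    column: str = "rr_ms",
) -> RRSeries:
    """Read an RR interval series from a text file.

    Parameters
    ----------
    path : path or open text stream
        Input file.  ``plain-ms``: one interval in milliseconds per line,
        ``#`` starts a comment.  ``csv-with-header``: a CSV with a header row
        containing an interval column (default ``rr_ms``) and an optional
        ``label`` column.
    dialect : {"plain-ms", "csv-with-header"}
    """
    if dialect not in ("plain-ms", "csv-with-header"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if record_id is None and isinstance(path, (str, Path)):
        record_id = Path(path).stem

    if dialect == "csv-with-header":
        df = pd.read_csv(path)
        if column not in df.columns:
            raise ValueError(f"CSV is missing the interval column {column!r}")
        intervals = df[column].to_numpy(dtype=float)
        labels = None
        if "label" in df.columns:
            labels = df["label"].astype(str).to_numpy()
        if intervals.size == 0:
            raise ValueError("no beats")
        return RRSeries(intervals, labels, record_id=record_id or "", moment=moment)

    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    values = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            v = float(line)
        except ValueError:
            raise ValueError(f"non-numeric RR value {line!r} at line {lineno}") from None
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"non-positive interval at line {lineno}")
        values.append(v)
    if not values:
        raise ValueError("no beats")
    return RRSeries(np.asarray(values), record_id=record_id or "", moment=moment)


def write_rr(series: RRSeries, path: Union[str, Path], dialect: str = "plain-ms") -> None:
    """Write a series in a format :func:`read_rr` reads back losslessly."""
    path = Path(path)
    if dialect == "plain-ms":
        path.write_text("".join(f"{v:.6f}\n" for v in series.intervals))
    elif dialect == "csv-with-header":
        pd.DataFrame(
            {"rr_ms": series.intervals, "label": series.beat_labels}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def adaptive_ectopic_filter(
    series: RRSeries,
    window: int = 10,
    z_threshold: float = 3.0,
    coeff: float = 0.05,
    basal_tol_ms: float = 20.0,
) -> RRSeries:
    """Replace ectopic/artifact beats with an adaptive running estimate.

    A running mean ``mu`` and running absolute deviation ``sigma`` are
    updated beat by beat with exponential coefficient ``coeff``.  A beat
    deviating from ``mu`` by more than ``z_threshold * sigma + basal_tol_ms``
    is labelled replaced and substituted by the current running mean; the
    running statistics are then updated with the substituted value, so a
    burst of ectopy cannot drag the estimate away.  Slow physiological trends
    are tracked by ``mu`` and therefore not flagged.

    Parameters
    ----------
    window : int
        Number of leading beats used to initialise the running statistics
        (median / mean absolute deviation), >= 3.
    z_threshold : float
        Multiples of the adaptive deviation tolerated before replacement.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    x = series.intervals
    if x.size < window + 1:
        raise ValueError(f"series needs at least window+1 = {window + 1} beats")

    out = x.copy()
    labels = series.beat_labels.copy()
    head = x[:window]
    mu = float(np.median(head))
    sigma = float(np.mean(np.abs(head - mu)))
    for t in range(x.size):
        if abs(x[t] - mu) > z_threshold * sigma + basal_tol_ms:
            out[t] = mu
            labels[t] = LABEL_REPLACED
        accepted = out[t]
        mu = (1.0 - coeff) * mu + coeff * accepted
        sigma = (1.0 - coeff) * sigma + coeff * abs(accepted - mu)
    return RRSeries(out, labels, record_id=series.record_id, moment=series.moment)


def exclusion_gate(
    series: RRSeries,
    min_duration: float = 300.0,
    max_replaced: float = 0.05,
) -> GateDecision:
    """Record-level inclusion decision.

    Excludes with reason ``"short"`` when total recording time is below
    ``min_duration`` seconds, and with reason ``"replacement"`` when more
    than ``max_replaced`` of the beats were substituted by the adaptive
    filter.  The decision depends only on duration and replaced fraction.
    """
    if series.total_duration < min_duration:
        return GateDecision(False, "short")
    if series.replaced_fraction > max_replaced:
        return GateDecision(False, "replacement")
    return GateDecision(True, None)


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort metadata CSV (record_id, prior_mi, sex, age)."""
    df = pd.read_csv(path)
    required = {"record_id", "prior_mi", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    ids = df["record_id"]
    if ids.duplicated().any():
        raise ValueError("record_id values must be unique")
    df = df.copy()
    df["prior_mi"] = df["prior_mi"].astype(bool)
    return df


def screening_summary(initial_n: int, excluded_counts: Sequence[int]) -> dict:
    """Bookkeeping of a screening cascade: initial sample minus exclusions.

    Returns a dict with ``initial``, ``excluded`` (total) and ``included``.
    """
    excluded = int(sum(int(c) for c in excluded_counts))
    if excluded > initial_n:
        raise ValueError("more exclusions than subjects")
    return {"initial": int(initial_n), "excluded": excluded, "included": int(initial_n) - excluded}
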