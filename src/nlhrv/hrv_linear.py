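"""Time-domain and frequency-domain HRV indices for short-term NN series.

Time domain: meanNN, SDNN (sample SD of the intervals) and SDSD (sample SD
of successive differences).  Frequency domain: the NN series is interpolated
with a cubic spline and resampled on a uniform 3 Hz grid, a segment-averaged
(Welch) periodogram with a 300-sample Hamming window and 50% overlap is
computed, and power is integrated over the conventional short-term bands:
VLF < 0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz.  Normalized units divide LF
and HF by total power minus VLF, so LF(n.u.) + HF(n.u.) = 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .preprocess import RRSeries

__all__ = [
    "SpectralEstimate",
    "LinearIndices",
    "time_domain",
    "resample_series",
    "welch_spectrum",
    "band_powers_and_nu",
    "linear_indices",
]

VLF_EDGE = 0.04
LF_EDGE = 0.15
HF_EDGE = 0.40


@dataclass
class SpectralEstimate:
    """A power spectral density of the resampled tachogram.

    ``power`` is a density in ms^2/Hz on ``frequencies`` (Hz);
    ``band_powers`` holds integrated VLF/LF/HF/total power in ms^2, with
    total defined over (0, 0.4] Hz (DC excluded) so the three bands sum to
    the total exactly.
    """

    frequencies: np.ndarray
    power: np.ndarray
    band_powers: dict
    settings: dict


@dataclass
class LinearIndices:
    mean_nn: float
    sdnn: float
    sdsd: float
    lf_ms2: float = np.nan
    hf_ms2: float = np.nan
    vlf_ms2: float = np.nan
    total_ms2: float = np.nan
    lf_nu: float = np.nan
    hf_nu: float = np.nan
    ln_lf: float = np.nan
    ln_hf: float = np.nan
    ln_lf_hf: float = np.nan
    flagged: bool = False


def time_domain(series: RRSeries) -> Tuple[float, float, float]:
    """Return (meanNN, SDNN, SDSD) in ms; sample SDs use the n-1 denominator."""
    x = series.intervals
    if x.size < 2:
        raise ValueError("time-domain indices need at least 2 beats")
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    d = np.diff(x)
    sdsd = float(np.std(d, ddof=1)) if d.size >= 2 else 0.0
    return mean_nn, sdnn, sdsd


def resample_series(series: RRSeries, rate: float = 3.0) -> Tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling of the tachogram on a uniform grid.

    The RR value is treated as a function of cumulative beat time and
    interpolated with a cubic spline, then sampled at ``rate`` Hz from the
    first to the last beat.  Returns ``(times_s, values_ms)``.
    """
    x = series.intervals
    if x.size < 4:
        raise ValueError("resampling needs at least 4 beats")
    t = series.beat_times
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing cumulative beat times")
    spline = CubicSpline(t, x)
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return grid, spline(grid)


def welch_spectrum(
    tachogram: np.ndarray,
    rate: float = 3.0,
    window_len: int = 300,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Segment-averaged Hamming-window periodogram of an evenly sampled tachogram.

    Per-segment mean removal only (no detrending), density scaling: the
    integral of the PSD over frequency approximates the windowed variance of
    the signal in ms^2.
    """
    x = np.asarray(tachogram, dtype=float)
    if x.size < window_len:
        raise ValueError(
            f"tachogram has {x.size} samples < window_len={window_len}; "
            "use a shorter window"
        )
    noverlap = int(round(window_len * overlap))
    freqs, psd = signal.welch(
        x,
        fs=rate,
        window="hamming",
        nperseg=window_len,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    est = SpectralEstimate(
        frequencies=freqs,
        power=psd,
        band_powers={},
        settings={"resample_rate": rate, "window_len": window_len, "overlap": overlap},
    )
    est.band_powers = _integrate_bands(freqs, psd)
    return est


def _integrate_bands(freqs: np.ndarray, psd: np.ndarray) -> dict:
    # Rectangle-rule integration on the FFT bin grid; assigning each bin to
    # exactly one band guarantees VLF + LF + HF == total.
    df = freqs[1] - freqs[0]
    p = psd * df
    in_total = (freqs > 0) & (freqs <= HF_EDGE)
    vlf = float(p[(freqs > 0) & (freqs < VLF_EDGE)].sum())
    lf = float(p[(freqs >= VLF_EDGE) & (freqs < LF_EDGE)].sum())
    hf = float(p[(freqs >= LF_EDGE) & (freqs <= HF_EDGE)].sum())
    total = float(p[in_total].sum())
    return {"VLF": vlf, "LF": lf, "HF": hf, "total": total}


def band_powers_and_nu(spec: SpectralEstimate) -> LinearIndices:
    """Band powers, normalized units and log transforms from a spectrum.

    ``lf_nu = 100 * LF / (total - VLF)`` and analogously for HF.  Records
    where ``total - VLF <= 0`` or ``HF == 0`` are flagged (normalized units /
    log ratio undefined).
    """
    bp = spec.band_powers
    vlf, lf, hf, total = bp["VLF"], bp["LF"], bp["HF"], bp["total"]
    out = LinearIndices(
        mean_nn=np.nan, sdnn=np.nan, sdsd=np.nan,
        lf_ms2=lf, hf_ms2=hf, vlf_ms2=vlf, total_ms2=total,
    )
    denom = total - vlf
    if denom <= 0:
        out.flagged = True
        return out
    out.lf_nu = 100.0 * lf / denom
    out.hf_nu = 100.0 * hf / denom
    out.ln_lf = float(np.log(lf)) if lf > 0 else np.nan
    out.ln_hf = float(np.log(hf)) if hf > 0 else np.nan
    if hf > 0 and lf > 0:
        out.ln_lf_hf = float(np.log(lf / hf))
    else:
        out.flagged = True
    return out


def linear_indices(
    series: RRSeries,
    rate: float = 3.0,
    window_len: int = 300,
    overlap: float = 0.5,
) -> LinearIndices:
    """All linear HRV indices of one record (time + frequency domain)."""
    mean_nn, sdnn, sdsd = time_domain(series)
    _, tach = resample_series(series, rate=rate)
    wl = min(window_len, tach.size)
    spec = welch_spectrum(tach, rate=rate, window_len=wl, overlap=overlap)
    out = band_powers_and_nu(spec)
    out.mean_nn, out.sdnn, out.sdsd = mean_nn, sdnn, sdsd
    return out
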