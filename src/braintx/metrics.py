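"""Resting-state regional metrics: ALFF, fALFF, and ReHo.

ALFF is the amplitude of low-frequency fluctuation: the periodogram
amplitude (square root of power) of a detrended voxel series summarized over
the 0.01-0.08 Hz band. fALFF is the fractional variant: in-band amplitude
divided by full-spectrum (DC excluded) amplitude. ReHo is regional
homogeneity: Kendall's coefficient of concordance W of the rank-transformed
time series across the voxels of a neighborhood, with the standard tie
correction:

    W = 12 * S / (V^2 (T^3 - T) - V * sum_v T_v)

where S is the sum of squared deviations of per-timepoint rank sums, V the
number of voxels, T the number of timepoints, and T_v the tie correction of
voxel v.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

DEFAULT_BAND = (0.01, 0.08)


def _as_block(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if ts.ndim != 2:
        raise ValueError("time series block must be 1-D or 2-D (T x V)")
    if not np.all(np.isfinite(ts)):
        raise ValueError("time series contains non-finite values")
    return ts


def _amplitude_spectrum(ts: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of each linearly detrended voxel series."""
    T = ts.shape[0]
    x = signal.detrend(ts, axis=0, type="linear")
    amp = np.abs(np.fft.rfft(x, axis=0)) * 2.0 / T
    freqs = np.fft.rfftfreq(T, d=tr)
    return freqs, amp


def _check_band(band: tuple[float, float], tr: float) -> None:
    lo, hi = band
    nyq = 0.5 / tr
    if not (0 < lo < hi <= nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high <= Nyquist ({nyq} Hz)")


def alff(
    ts: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
    agg: str = "mean",
) -> np.ndarray:
    """Per-voxel amplitude of low-frequency fluctuation.

    ``agg`` chooses the in-band summary ("mean" of bin amplitudes, the
    default, or "sum"). A region-level value is the mean across voxels.
    """
    ts = _as_block(ts)
    _check_band(band, tr)
    freqs, amp = _amplitude_spectrum(ts, tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("frequency band contains no spectral bins; series too short")
    if agg == "mean":
        return amp[mask].mean(axis=0)
    if agg == "sum":
        return amp[mask].sum(axis=0)
    raise ValueError(f"unknown agg {agg!r}")


def falff(
    ts: np.ndarray, tr: float, band: tuple[float, float] = DEFAULT_BAND
) -> np.ndarray:
    """Per-voxel fractional ALFF: in-band over full-spectrum amplitude, in [0, 1]."""
    ts = _as_block(ts)
    _check_band(band, tr)
    freqs, amp = _amplitude_spectrum(ts, tr)
    nondc = freqs > 0
    total = amp[nondc].sum(axis=0)
    if np.any(total == 0):
        raise ValueError("zero total spectral power: fALFF undefined")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return amp[mask].sum(axis=0) / total


def reho(ts: np.ndarray) -> float:
    """Kendall's W of the voxel rank series, tie-corrected; in [0, 1]."""
    ts = _as_block(ts)
    T, V = ts.shape
    if V < 2 or T < 2:
        raise ValueError("ReHo needs at least 2 voxels and 2 timepoints")

    ranks = np.apply_along_axis(stats.rankdata, 0, ts)
    rank_sums = ranks.sum(axis=1)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())

    tie_corr = 0.0
    for v in range(V):
        _, counts = np.unique(ts[:, v], return_counts=True)
        tie_corr += float((counts**3 - counts).sum())
    denom = V**2 * (T**3 - T) - V * tie_corr
    if denom <= 0:
        raise ValueError("degenerate block (all series constant): ReHo undefined")
    return 12.0 * S / denom


def metric_map(
    blocks: dict[str, np.ndarray], tr: float, metric: str, **kwargs
) -> dict[str, float]:
    """Apply one metric to a dict of region -> T x V blocks; voxel metrics are averaged."""
    out = {}
    for region, block in blocks.items():
        if metric == "alff":
            out[region] = float(np.mean(alff(block, tr, **kwargs)))
        elif metric == "falff":
            out[region] = float(np.mean(falff(block, tr, **kwargs)))
        elif metric == "reho":
            out[region] = reho(block)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def zscore_map(values: np.ndarray) -> np.ndarray:
    """Z-standardize a metric map across regions (done before group analysis)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("constant map cannot be z-standardized")
    return (values - values.mean()) / sd


__all__ = ["DEFAULT_BAND", "alff", "falff", "metric_map", "reho", "zscore_map"]
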