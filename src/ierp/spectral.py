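"""Instantaneous frequency of IMFs and data-driven mode-range selection.

Each IMF is a narrowband oscillation, so its instantaneous frequency (IF)
— the time derivative of the analytic-signal phase — is well defined and
concentrates around the IMF's characteristic scale.  The *representative
frequency* of an IMF is the IF value with maximum occurrence probability,
read off a log-spaced histogram.  Tabulating representative frequencies
per IMF order across trials, channels and subjects is the standard
diagnostic for order/time-scale consistency: if the distributions per
order are tight and strictly ordered, the IMF order is a meaningful
frequency axis and the mode lattice can be shared across units.

The same per-order medians drive the choice of which orders enter the
mode lattice: orders whose median representative frequency is at or above
``hi_cut`` (default 30 Hz, the conventional ERP low-pass edge) are
excluded, and orders at or below ``lo_cut`` (default 2 Hz, the bottom of
the delta band) are aggregated into a single slow "trend" block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .ceemdan import IMFStack

__all__ = [
    "IFSeries",
    "ModeRange",
    "instantaneous_frequency",
    "representative_frequency",
    "if_consistency_summary",
    "select_mode_range",
    "IF_HIST_BINS",
]

#: Log-spaced histogram bin edges (Hz) for representative frequencies:
#: 48 bins spanning 0.25-64 Hz, i.e. 6 bins per octave over 8 octaves.
IF_HIST_BINS = np.logspace(np.log2(0.25), np.log2(64.0), 49, base=2.0)


@dataclass
class IFSeries:
    """Instantaneous frequency per sample (Hz) of one IMF."""

    if_values: np.ndarray
    order: int = 0
    degenerate: bool = False  # all-zero source signal


@dataclass(frozen=True)
class ModeRange:
    """Orders entering the mode lattice.

    ``p_min`` is the first (fastest) included order; ``trend_start`` is
    the first order folded into the slow trend block.  Orders above
    ``trend_start`` never appear individually.
    """

    p_min: int
    trend_start: int
    hi_cut: float = 30.0
    lo_cut: float = 2.0

    def __post_init__(self):
        if not 1 <= self.p_min <= self.trend_start:
            raise ValueError("need 1 <= p_min <= trend_start")

    @property
    def n_lattice_orders(self) -> int:
        """M, the number of lattice rows/columns (trend block counts as one)."""
        return self.trend_start - self.p_min + 1


def instantaneous_frequency(imf, fs: float) -> IFSeries:
    """IF via the analytic signal: unwrapped Hilbert phase, centred
    difference, clipped to [0, fs/2]."""
    x = np.asarray(imf, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("IMF contains non-finite values")
    if np.all(x == 0):
        return IFSeries(if_values=np.zeros_like(x), degenerate=True)
    phase = np.unwrap(np.angle(hilbert(x)))
    inst = np.gradient(phase) * fs / (2.0 * np.pi)
    return IFSeries(if_values=np.clip(inst, 0.0, fs / 2.0))


def representative_frequency(ifs) -> float:
    """Mode of the IF distribution over log-spaced bins (0.25-64 Hz).

    Accepts one IFSeries, an array of IF values, or a collection of
    either; all samples are pooled.  Values outside the bin range are
    clipped into the edge bins so a pure tone outside the range still
    reports the nearest representable frequency.
    """
    values = _pool_if_values(ifs)
    if values.size == 0:
        raise ValueError("no IF values supplied")
    clipped = np.clip(values, IF_HIST_BINS[0] * (1 + 1e-9),
                      IF_HIST_BINS[-1] * (1 - 1e-9))
    counts, _ = np.histogram(clipped, bins=IF_HIST_BINS)
    i = int(np.argmax(counts))
    return float(np.sqrt(IF_HIST_BINS[i] * IF_HIST_BINS[i + 1]))


def _pool_if_values(ifs) -> np.ndarray:
    if isinstance(ifs, IFSeries):
        return np.asarray(ifs.if_values, float).ravel()
    if isinstance(ifs, np.ndarray):
        return ifs.astype(float).ravel()
    parts = [_pool_if_values(x) for x in ifs]
    if not parts:
        return np.array([])
    return np.concatenate(parts)


def representative_frequencies(stack: IMFStack) -> np.ndarray:
    """Representative frequency per (trial, channel, order 1..K)."""
    n_trials, n_channels = stack.n_trials, stack.n_channels
    out = np.zeros((n_trials, n_channels, stack.K))
    for t in range(n_trials):
        for ch in range(n_channels):
            for k in range(stack.K):
                series = instantaneous_frequency(stack.values[t, ch, k], stack.fs)
                if series.degenerate:
                    out[t, ch, k] = np.nan
                else:
                    out[t, ch, k] = representative_frequency(series)
    return out


def if_consistency_summary(stack: IMFStack,
                           quantiles=(5, 25, 50, 75, 95)) -> pd.DataFrame:
    """Across-trial quantiles of representative frequency per order and
    channel — the box-and-whisker consistency diagnostic, as a tidy
    table (order, channel, quantile, hz)."""
    rep = representative_frequencies(stack)
    rows = []
    for ch in range(stack.n_channels):
        for k in range(stack.K):
            vals = rep[:, ch, k]
            vals = vals[np.isfinite(vals)]
            for q in quantiles:
                hz = float(np.percentile(vals, q)) if vals.size else np.nan
                rows.append({"order": k + 1, "channel": ch,
                             "quantile": q, "hz": hz})
    return pd.DataFrame(rows)


def order_median_frequencies(stack: IMFStack) -> np.ndarray:
    """Dataset-wide median representative frequency per order 1..K."""
    rep = representative_frequencies(stack)
    return np.nanmedian(rep.reshape(-1, stack.K), axis=0)


def _range_from_medians(medians: np.ndarray, hi_cut: float,
                        lo_cut: float) -> tuple[int, int]:
    """(p_min, trend_start) from per-order median frequencies.

    p_min: lowest order with median < hi_cut.  trend_start: lowest order
    with median < lo_cut, or K + 1 (the residue alone forms the trend)
    when no order is that slow.
    """
    medians = np.asarray(medians, dtype=float)
    below_hi = np.nonzero(medians < hi_cut)[0]
    if below_hi.size == 0:
        raise ValueError(f"no IMF order has median frequency below {hi_cut} Hz; "
                         "raise hi_cut or check the decomposition depth")
    p_min = int(below_hi[0]) + 1
    below_lo = np.nonzero(medians < lo_cut)[0]
    trend_start = int(below_lo[0]) + 1 if below_lo.size else medians.size + 1
    trend_start = max(trend_start, p_min)
    return p_min, trend_start


def select_mode_range(stack: IMFStack, hi_cut: float = 30.0,
                      lo_cut: float = 2.0) -> ModeRange:
    """Data-driven lattice bounds from the stack's per-order median
    representative frequencies."""
    medians = order_median_frequencies(stack)
    p_min, trend_start = _range_from_medians(medians, hi_cut, lo_cut)
    return ModeRange(p_min=p_min, trend_start=trend_start,
                     hi_cut=hi_cut, lo_cut=lo_cut)
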