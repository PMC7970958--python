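"""The iERP mode lattice: trial-averaged pure and composite modes.

A *pure* mode p:p is the trial average of the p-th IMF; a *composite*
mode p:q (p < q) averages the partial sum of IMFs p..q.  All orders from
``trend_start`` up to and including the residue are folded into a single
slow "trend" block, written with a trailing ``+`` (e.g. ``6+``), so a
lattice over orders p_min..trend_start has M = trend_start - p_min + 1
rows and M(M+1)/2 modes in total.  Because averaging is linear, every
composite mode equals the sum of its pure constituents exactly — the
lattice is a redundant *representation*, not a decomposition, and that
redundancy is what the XOR neighbour rule exploits downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ceemdan import IMFStack
from .spectral import ModeRange

__all__ = [
    "ModeLabel",
    "ModeTensor",
    "make_mode_labels",
    "form_ierp_modes",
    "baseline_correct",
    "time_bin",
]

#: Sentinel used inside constituent sets for the aggregated trend block.
TREND = -1


@dataclass(frozen=True)
class ModeLabel:
    """A mode p:q, with ``trend=True`` when q is the trend block.

    ``constituents(trend_as_block=True)`` gives the set the XOR
    neighbour rule operates on: plain orders p..q, with the whole trend
    block represented by the single pseudo-ordinal ``trend_start`` (or
    expanded to the individual slow orders when ``trend_as_block=False``,
    in which case ``k_plus_1`` must be supplied).
    """

    p: int
    q: int
    trend: bool = False

    def __post_init__(self):
        if self.p > self.q:
            raise ValueError("need p <= q")

    def __str__(self) -> str:
        if self.trend:
            return f"{self.p}:{self.q}+" if self.p < self.q else f"{self.q}+"
        return f"{self.p}:{self.q}"

    def constituents(self, trend_as_block: bool = True,
                     k_plus_1: int | None = None) -> frozenset[int]:
        if not self.trend:
            return frozenset(range(self.p, self.q + 1))
        base = frozenset(range(self.p, self.q))
        if trend_as_block:
            return base | {self.q}
        if k_plus_1 is None:
            raise ValueError("k_plus_1 required to expand the trend block")
        return base | frozenset(range(self.q, k_plus_1 + 1))

    def orders(self, k_plus_1: int) -> list[int]:
        """The IMF-stack orders (1-based, residue = K+1) summed into
        this mode."""
        if self.trend:
            return list(range(self.p, k_plus_1 + 1))
        return list(range(self.p, self.q + 1))


def make_mode_labels(mode_range: ModeRange) -> list[ModeLabel]:
    """All M(M+1)/2 modes of the lattice, lexicographic in (p, q) with
    the trend mode closing each p-row."""
    p_min, ts = mode_range.p_min, mode_range.trend_start
    labels: list[ModeLabel] = []
    for p in range(p_min, ts + 1):
        for q in range(p, ts + 1):
            labels.append(ModeLabel(p=p, q=q, trend=(q == ts)))
    return labels


@dataclass
class ModeTensor:
    """Trial-averaged mode waveforms: values[mode, channel, time] (µV)."""

    values: np.ndarray
    mode_labels: list[ModeLabel]
    times: np.ndarray
    fs: float
    n_trials: int
    condition: str = ""
    subject: str = ""
    k_plus_1: int = 0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.shape[0] != len(self.mode_labels):
            raise ValueError("one label per mode required")
        if self.values.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]

    def mode(self, label) -> np.ndarray:
        s = str(label)
        for i, lab in enumerate(self.mode_labels):
            if str(lab) == s:
                return self.values[i]
        raise KeyError(f"no mode {s!r}")

    def copy_with(self, values: np.ndarray, times=None) -> "ModeTensor":
        return ModeTensor(values=values, mode_labels=self.mode_labels,
                          times=self.times if times is None else times,
                          fs=self.fs, n_trials=self.n_trials,
                          condition=self.condition, subject=self.subject,
                          k_plus_1=self.k_plus_1,
                          channel_labels=self.channel_labels)


def form_ierp_modes(stack: IMFStack, conditions, mode_range: ModeRange,
                    times=None, subject: str = "",
                    channel_labels=None) -> dict[str, ModeTensor]:
    """Average every lattice mode over trials, per condition.

    For each mode the constituent IMF orders are summed within each
    trial first, then averaged over the condition's trials; for trend
    modes the sum runs through the residue (order K+1).
    """
    conditions = np.asarray(conditions)
    if conditions.shape[0] != stack.n_trials:
        raise ValueError("one condition label per trial required")
    labels = make_mode_labels(mode_range)
    k_plus_1 = stack.K + 1
    if mode_range.trend_start > k_plus_1:
        raise ValueError("trend_start exceeds the stack's K + 1")
    if times is None:
        times = np.arange(stack.n_times) / stack.fs
    out: dict[str, ModeTensor] = {}
    for cond in dict.fromkeys(str(c) for c in conditions):
        mask = conditions.astype(str) == cond
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no trials")
        sub = stack.values[mask]                       # (nt, nc, K+1, T)
        values = np.empty((len(labels), stack.n_channels, stack.n_times))
        for i, lab in enumerate(labels):
            orders = np.array(lab.orders(k_plus_1)) - 1
            values[i] = sub[:, :, orders, :].sum(axis=2).mean(axis=0)
        out[cond] = ModeTensor(values=values, mode_labels=labels,
                               times=np.asarray(times, float), fs=stack.fs,
                               n_trials=int(mask.sum()), condition=cond,
                               subject=subject, k_plus_1=k_plus_1,
                               channel_labels=list(channel_labels or []))
    return out


def baseline_correct(modes: ModeTensor, window: tuple[float, float]) -> ModeTensor:
    """Subtract the per-mode, per-channel mean over ``window`` (seconds,
    half-open [t0, t1))."""
    t0, t1 = window
    mask = (modes.times >= t0) & (modes.times < t1)
    if not mask.any():
        raise ValueError(f"baseline window [{t0}, {t1}) contains no samples")
    baseline = modes.values[:, :, mask].mean(axis=2, keepdims=True)
    return modes.copy_with(modes.values - baseline)


def time_bin(modes: ModeTensor, bin_width: float,
             span: tuple[float, float],
             warn_fast_modes: bool = True) -> ModeTensor:
    """Average into contiguous bins of ``bin_width`` seconds over
    ``span``; a partial trailing bin is dropped.  The returned time axis
    holds bin centres.

    Modes whose fastest constituent oscillates with a period shorter
    than the bin width largely average out within a bin; when
    ``warn_fast_modes`` and the sampling rate implies such orders exist,
    a warning names them (exclusion is left to the caller).
    """
    t0, t1 = span
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("span shorter than one bin")
    edges = t0 + bin_width * np.arange(n_bins + 1)
    values = np.empty((modes.n_modes, modes.values.shape[1], n_bins))
    centers = 0.5 * (edges[:-1] + edges[1:])
    for b in range(n_bins):
        mask = (modes.times >= edges[b]) & (modes.times < edges[b + 1])
        if not mask.any():
            raise ValueError("bin without samples; bin_width below 1/fs?")
        values[:, :, b] = modes.values[:, :, mask].mean(axis=2)
    if warn_fast_modes:
        _warn_fast_modes(modes, bin_width)
    binned = modes.copy_with(values, times=centers)
    return binned


def _warn_fast_modes(modes: ModeTensor, bin_width: float) -> None:
    # order k of a dyadic bank at rate fs oscillates near fs / 2**(k+1);
    # flag modes whose fastest order has period < bin_width.
    fast = []
    for lab in modes.mode_labels:
        approx_hz = modes.fs / 2.0 ** (lab.p + 1)
        if approx_hz > 0 and 1.0 / approx_hz < bin_width:
            fast.append(str(lab))
    if fast:
        warnings.warn(
            "bin width exceeds the approximate period of the fastest "
            f"constituent of modes {fast}; consider excluding them",
            RuntimeWarning, stacklevel=3)
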