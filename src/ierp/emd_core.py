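"""Plain empirical mode decomposition (EMD).

EMD decomposes a 1-D signal into intrinsic mode functions (IMFs) by
iteratively *sifting*: the local mean of the cubic-spline envelopes through
the maxima and minima is subtracted until the candidate oscillates
symmetrically about zero.  An IMF has (i) extrema and zero-crossing counts
that differ by at most one, and (ii) a near-zero envelope mean everywhere.
Successive IMFs capture successively slower oscillations; on broadband
noise the decomposition acts as a dyadic filter bank, so roughly log2(N)
IMFs emerge from N samples.

The sifting count is fixed at 10 iterations per IMF.  A fixed count (rather
than a Cauchy-style convergence test) keeps the filter bank dyadic on white
noise and makes the output deterministic, which downstream ensemble
averaging relies on.

Boundary treatment: before fitting the envelopes, two extrema at each end
are mirror-reflected past the signal edges.  This is a standard guard
against spline end swings; the envelopes are only evaluated on the original
support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._emd_kernels import (_mirror_knots, find_extrema_nb, sift_nb,
                           spline_envelope_nb)

__all__ = [
    "Signal",
    "IMFList",
    "InsufficientExtremaError",
    "find_extrema",
    "envelope_mean",
    "sift_imf",
    "emd",
    "emd_mode_k",
    "N_SIFTS_DEFAULT",
]

#: Fixed sifting count per IMF.
N_SIFTS_DEFAULT = 10


class InsufficientExtremaError(ValueError):
    """Raised when a spline envelope cannot be built (fewer than two
    maxima or two minima even after boundary extension)."""


@dataclass(frozen=True)
class Signal:
    """A finite real-valued series with its sampling rate in Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 8:
            raise ValueError("signal must be 1-D with at least 8 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class IMFList:
    """Ordered IMFs ``c_1 .. c_n`` plus the final residue ``r_n``.

    The decomposition identity ``x = sum(imfs) + residue`` holds to
    machine precision by construction (each IMF is subtracted from the
    running residue, so the sum telescopes).
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sifts_used: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out


def _as_array(signal) -> np.ndarray:
    if isinstance(signal, Signal):
        return signal.samples
    return np.asarray(signal, dtype=float)


def find_extrema(signal) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strictly interior local maxima and minima.

    Plateaus (runs of equal values bounded by strictly lower / higher
    neighbours) contribute a single extremum at the integer midpoint of the
    run, which keeps the output deterministic.  Endpoints are never
    extrema.

    Returns
    -------
    (maxima, minima) : pair of int arrays, ascending.
    """
    x = _as_array(signal)
    if x.size < 3:
        return np.array([], dtype=np.intp), np.array([], dtype=np.intp)
    maxima, minima = find_extrema_nb(x)
    return maxima.astype(np.intp), minima.astype(np.intp)


def _envelope(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    xi, yi = _mirror_knots(idx.astype(np.int64), vals, n)
    if xi.size < 2:
        raise InsufficientExtremaError("fewer than 2 envelope knots")
    return spline_envelope_nb(xi, yi, n)


def envelope_mean(signal, maxima: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Pointwise mean of the upper and lower cubic-spline envelopes.

    Raises
    ------
    InsufficientExtremaError
        If either envelope has fewer than two knots after mirror
        extension.
    """
    x = _as_array(signal)
    maxima = np.asarray(maxima, dtype=np.intp)
    minima = np.asarray(minima, dtype=np.intp)
    if maxima.size < 1 or minima.size < 1:
        raise InsufficientExtremaError("need at least one maximum and one minimum")
    upper = _envelope(maxima, x[maxima], x.size)
    lower = _envelope(minima, x[minima], x.size)
    return 0.5 * (upper + lower)


def sift_imf(signal, n_sifts: int = N_SIFTS_DEFAULT) -> np.ndarray:
    """Extract one IMF candidate by ``n_sifts`` envelope-mean subtractions.

    Sifting stops early (without error) if the running candidate loses its
    extrema; the number of sifts actually performed is available through
    :func:`sift_imf_full`.
    """
    h, _ = sift_imf_full(signal, n_sifts)
    return h


def sift_imf_full(signal, n_sifts: int = N_SIFTS_DEFAULT) -> tuple[np.ndarray, int]:
    """As :func:`sift_imf` but also returns the sift count used."""
    if n_sifts < 1:
        raise ValueError("n_sifts must be >= 1")
    h, used = sift_nb(_as_array(signal).copy(), n_sifts)
    return h, used


def _n_extrema(x: np.ndarray) -> int:
    mx, mn = find_extrema(x)
    return mx.size + mn.size


def emd(signal, max_imfs: int | None = None,
        n_sifts: int = N_SIFTS_DEFAULT) -> IMFList:
    """Full EMD: peel IMFs off successive residues.

    Iteration stops when the residue has no more than two extrema (it is
    then monotone or a single hump, from which no oscillation can be
    sifted) or when ``max_imfs`` IMFs have been extracted.
    """
    x = _as_array(signal)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    sifts: list[int] = []
    while _n_extrema(residue) > 2:
        if max_imfs is not None and len(imfs) >= max_imfs:
            break
        c, used = sift_imf_full(residue, n_sifts)
        if used == 0:
            break
        imfs.append(c)
        sifts.append(used)
        residue = residue - c
    return IMFList(imfs=imfs, residue=residue, n_sifts_used=sifts)


def emd_mode_k(signal, k: int, n_sifts: int = N_SIFTS_DEFAULT) -> np.ndarray:
    """The ``E_k`` operator: the k-th EMD mode of ``signal``.

    Returns zeros (with a warning) when the decomposition yields fewer
    than ``k`` IMFs.
    """
    if k < 1:
        raise ValueError("mode order k must be >= 1")
    result = emd(signal, max_imfs=k, n_sifts=n_sifts)
    if result.n_imfs < k:
        warnings.warn(f"signal has only {result.n_imfs} IMFs; E_{k} is zero",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(_as_array(signal).size)
    return result.imfs[k - 1]
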