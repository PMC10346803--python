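"""Empirical mode decomposition by sifting.

EMD writes a signal x[n] as a sum of intrinsic mode functions plus a
residue, x[n] = sum_i IMF_i[n] + r[n], extracting each IMF by iteratively
subtracting the mean of the cubic-spline envelopes of the local maxima and
minima until the candidate (a) has zero-crossing and extrema counts equal
or differing by one and (b) has a near-zero envelope mean.  The
decomposition is ordered high to low frequency; EHG analysis here keeps the
first four IMFs, where contraction energy concentrates.

Numerical choices (the classical sifting procedure leaves these open):

* stopping — Cauchy criterion ``SD_k = sum((y_{k-1}-y_k)^2)/sum(y_{k-1}^2)
  < 0.2`` or envelope-mean ratio ``mean|m|/mean|y| < 0.01``, in either case
  together with the count condition; hard cap of 100 sift iterations
  guards against over-sifting;
* envelopes — natural cubic splines through the extrema, with the first and
  last two extrema mirrored about the signal ends to tame end effects;
* plateaus of equal samples collapse to a single extremum at their
  floor-midpoint index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger("ehgpreterm")

__all__ = ["SiftStopRule", "IMFSet", "MonotoneResidueError",
           "find_extrema", "envelope_mean", "sift_one_imf", "decompose",
           "count_zero_crossings", "is_imf"]


class MonotoneResidueError(Exception):
    """Too few extrema to build envelopes: the signal is a residue."""


@dataclass(frozen=True)
class SiftStopRule:
    """When to accept a sifting candidate as an IMF."""

    sd_tol: float = 0.2
    env_ratio_tol: float = 0.01
    max_iter: int = 100


@dataclass
class IMFSet:
    """Ordered IMFs plus residue for one channel; reconstructs the source."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    source_len: int
    sift_counts: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def __len__(self) -> int:
        return len(self.imfs)


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima and minima indices, plateaus collapsed.

    A run of equal samples bounded by opposite slopes counts as a single
    extremum at the floor midpoint of the run.  Returned arrays alternate
    by construction and never include the endpoints.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    d = np.diff(x)
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    flips = np.nonzero(s[:-1] != s[1:])[0]
    if flips.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    starts = nz[flips] + 1          # first index of the extremal run
    ends = nz[flips + 1]            # last index of the extremal run
    idx = (starts + ends) // 2      # floor-midpoint plateau rule
    is_max = s[flips] > 0
    return idx[is_max], idx[~is_max]


def count_zero_crossings(x: np.ndarray) -> int:
    """Sign changes, ignoring exact zeros between opposite signs once."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def is_imf(x: np.ndarray) -> bool:
    """Count condition: |#extrema - #zero-crossings| <= 1."""
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    return abs(n_ext - count_zero_crossings(x)) <= 1


def _mirrored_spline(indices: np.ndarray, values: np.ndarray,
                     n: int) -> CubicSpline:
    """Natural cubic spline through extrema, first/last two mirrored about
    the signal ends so the envelope is defined on [0, n)."""
    left_i = -indices[1::-1][:2]
    left_v = values[1::-1][:2]
    right_i = 2 * (n - 1) - indices[-1:-3:-1]
    right_v = values[-1:-3:-1]
    knots = np.concatenate([left_i, indices, right_i])
    vals = np.concatenate([left_v, values, right_v])
    keep = np.concatenate([[True], np.diff(knots) > 0])
    return CubicSpline(knots[keep], vals[keep], bc_type="natural")


def envelope_mean(x: np.ndarray, maxima: np.ndarray,
                  minima: np.ndarray) -> np.ndarray:
    """Pointwise mean of the upper and lower cubic-spline envelopes."""
    x = np.asarray(x, dtype=float)
    if maxima.size < 2 or minima.size < 2:
        raise MonotoneResidueError(
            f"need >=2 maxima and minima, got {maxima.size}/{minima.size}")
    n = x.size
    grid = np.arange(n)
    upper = _mirrored_spline(maxima, x[maxima], n)(grid)
    lower = _mirrored_spline(minima, x[minima], n)(grid)
    return 0.5 * (upper + lower)


def sift_one_imf(x: np.ndarray,
                 stop: SiftStopRule = SiftStopRule(),
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract one IMF from ``x``; returns (imf, residue, n_iterations).

    Raises :class:`MonotoneResidueError` if the signal has too few extrema
    to sift at all.  If the iteration cap is hit, the current candidate is
    returned with a logged warning (standard practice: a slightly
    under-sifted mode beats an over-smoothed one).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sift_one_imf: non-finite samples")
    y = x
    for k in range(1, stop.max_iter + 1):
        maxima, minima = find_extrema(y)
        try:
            m = envelope_mean(y, maxima, minima)
        except MonotoneResidueError:
            if k == 1:
                raise
            break  # candidate degenerated; accept previous iterate
        y_new = y - m
        denom = np.sum(y * y)
        sd = np.sum(m * m) / denom if denom > 0 else 0.0
        cand_mean = np.mean(np.abs(y_new))
        env_ratio = (np.mean(np.abs(m)) / cand_mean
                     if cand_mean > 0 else 0.0)
        y = y_new
        if (sd < stop.sd_tol or env_ratio < stop.env_ratio_tol) and is_imf(y):
            return y, x - y, k
    else:
        logger.warning("sifting hit the %d-iteration cap", stop.max_iter)
        k = stop.max_iter
    return y, x - y, k


def decompose(x: np.ndarray, max_imfs: int = 4,
              stop: SiftStopRule = SiftStopRule()) -> IMFSet:
    """Decompose ``x`` into at most ``max_imfs`` IMFs plus a residue.

    Stops early once the running residue is (near-)monotone.  The residue
    is whatever remains, so reconstruction is exact by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 100:
        raise ValueError(f"decompose: signal too short ({x.size} samples)")
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residue = x.copy()
    for _ in range(max_imfs):
        try:
            imf, residue, k = sift_one_imf(residue, stop)
        except MonotoneResidueError:
            break
        imfs.append(imf)
        counts.append(k)
    return IMFSet(imfs, residue, x.size, counts)
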