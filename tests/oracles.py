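"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (loops, direct formula evaluation)
and shares no code with the package: a disagreement implicates one side.
"""

from itertools import combinations
from math import comb, log, log2, sqrt

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import rankdata


# -- scalar features --------------------------------------------------------

def rms_naive(x):
    total = 0.0
    for v in x:
        total += v * v
    return sqrt(total / len(x))


def mtke_naive(x):
    total = 0.0
    for n in range(1, len(x) - 1):
        total += x[n] ** 2 - x[n - 1] * x[n + 1]
    return total / (len(x) - 2)


def wle_naive(x, eps=1e-12):
    return sum(log(v * v + eps) for v in x)


def shannon_entropy_naive(x, n_bins=128):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    counts = [0] * n_bins
    for v in x:
        k = int((v - lo) / (hi - lo) * n_bins)
        counts[min(k, n_bins - 1)] += 1
    total = len(x)
    return -sum((c / total) * log2(c / total) for c in counts if c)


def kfd_naive(x):
    curve = sum(abs(x[i] - x[i - 1]) for i in range(1, len(x)))
    diam = max(abs(x[0] - x[j]) for j in range(1, len(x)))
    denom = log(len(x) - 1) + log(diam / curve)
    return 1.0 if denom == 0 else log(len(x) - 1) / denom


def hurst_naive(x):
    n = len(x)
    mean = sum(x) / n
    sd = sqrt(sum((v - mean) ** 2 for v in x) / n)
    cum, profile = 0.0, []
    for v in x:
        cum += v - mean
        profile.append(cum)
    r = max(profile) - min(profile)
    return log(r / sd) / log(n)


# -- Mann-Whitney -----------------------------------------------------------

def mann_whitney_exact_naive(a, b):
    """(U_min, exact two-sided p) by enumerating every group assignment."""
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1, n = len(a), len(pooled)
    ranks = rankdata(pooled)

    def u_min(idx):
        r1 = sum(ranks[i] for i in idx)
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, n1 * (n - n1) - u1)

    observed = u_min(range(n1))
    hits = sum(1 for idx in combinations(range(n), n1)
               if u_min(idx) <= observed + 1e-12)
    return observed, hits / comb(n, n1)


# -- naive sifting (independent EMD route) ----------------------------------

def _extrema_naive(y):
    ma, mi = [], []
    n, i = len(y), 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j + 1 < n:
            if y[i] > y[i - 1] and y[i] > y[j + 1]:
                ma.append((i + j) // 2)
            if y[i] < y[i - 1] and y[i] < y[j + 1]:
                mi.append((i + j) // 2)
        i = j + 1 if j > i else i + 1
    return ma, mi


def _envelope_naive(y, idx):
    n = len(y)
    ks = [-idx[1], -idx[0]] + list(idx) + [2 * (n - 1) - idx[-1],
                                           2 * (n - 1) - idx[-2]]
    vs = ([y[idx[1]], y[idx[0]]] + [y[k] for k in idx]
          + [y[idx[-1]], y[idx[-2]]])
    pairs = sorted(set(zip(ks, vs)))
    return CubicSpline([p[0] for p in pairs], [p[1] for p in pairs],
                       bc_type="natural")(np.arange(n))


def _zero_crossings_naive(y):
    signs = [v for v in np.sign(y) if v != 0]
    return sum(1 for i in range(1, len(signs)) if signs[i] != signs[i - 1])


def imf1_naive(x, sd_tol=0.2, env_tol=0.01, max_iter=100):
    """First IMF by the same published sifting procedure, coded from the
    algorithm description with explicit loops."""
    y = np.asarray(x, float)
    for _ in range(max_iter):
        ma, mi = _extrema_naive(y)
        if len(ma) < 2 or len(mi) < 2:
            break
        m = 0.5 * (_envelope_naive(y, ma) + _envelope_naive(y, mi))
        y_new = y - m
        sd = float(np.sum(m * m) / np.sum(y * y))
        mean_abs = float(np.mean(np.abs(y_new)))
        ratio = float(np.mean(np.abs(m))) / mean_abs if mean_abs else 0.0
        y = y_new
        ma2, mi2 = _extrema_naive(y)
        count_ok = abs(len(ma2) + len(mi2) - _zero_crossings_naive(y)) <= 1
        if (sd < sd_tol or ratio < env_tol) and count_ok:
            break
    return y
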