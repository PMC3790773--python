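"""Matched-pairs signed-rank machinery and the polynomial error function.

The caller compares normalized case and control per-exon coverages with a
non-parametric Wilcoxon matched-pairs test.  Two p-value routes exist:

* ``N_r > 10``  -- normal approximation with Yates continuity correction,
  z = (|W| - 0.5) / sigma_w,  sigma_w = sqrt(N_r(N_r+1)(2N_r+1)/6), and a
  two-sided p = 1 - erf(z / sqrt(2)) evaluated with the Abramowitz & Stegun
  7.1.26 polynomial (absolute error <= 1.5e-7).
* ``0 < N_r <= 10`` -- exact sampling distribution by enumerating all 2^N_r
  equiprobable sign assignments of the observed ranks (ties preserved),
  p = P(|W'| >= |W|).

``N_r`` counts the pairs with non-zero difference; zero differences are
discarded before ranking, and tied |d| receive mid-ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

__all__ = [
    "WilcoxonResult",
    "approximate_erf",
    "wilcoxon_matched_pairs",
    "windowed_wilcoxon",
    "exact_tail_table",
]

# Abramowitz & Stegun 7.1.26 coefficients.
_A1 = 0.254829592
_A2 = -0.284496736
_A3 = 1.421413741
_A4 = -1.453152027
_A5 = 1.061405429
_Q = 0.3275911

_EXACT_MAX_N = 10


def approximate_erf(x):
    """Polynomial approximation of the error function (A&S 7.1.26).

    Accepts scalars or arrays; odd symmetry is used for negative arguments.
    Maximum absolute error 1.5e-7.
    """
    x = np.asarray(x, dtype=float)
    sign = np.sign(x)
    ax = np.abs(x)
    t = 1.0 / (1.0 + _Q * ax)
    poly = t * (_A1 + t * (_A2 + t * (_A3 + t * (_A4 + t * _A5))))
    y = 1.0 - poly * np.exp(-ax * ax)
    out = sign * y
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of one matched-pairs signed-rank test."""

    n_pairs: int
    n_nonzero: int
    W: float
    sigma_w: float
    z: float
    p_value: float
    method: str  # "exact" | "normal_approx" | "degenerate"


def _sigma_w(n_r: int) -> float:
    return np.sqrt(n_r * (n_r + 1) * (2 * n_r + 1) / 6.0)


def _normal_p(abs_w, n_r):
    """Two-sided p via the continuity-corrected z and the polynomial erf."""
    sigma = np.sqrt(np.asarray(n_r, dtype=float) * (np.asarray(n_r) + 1)
                    * (2 * np.asarray(n_r) + 1) / 6.0)
    z = np.maximum(np.asarray(abs_w, dtype=float) - 0.5, 0.0) / sigma
    return 1.0 - approximate_erf(z / np.sqrt(2.0))


def _exact_p_from_ranks(ranks: np.ndarray, abs_w: float) -> float:
    """P(|W'| >= |W|) over all 2^n sign assignments of the given ranks."""
    n = len(ranks)
    # bit matrix of all sign patterns: shape (2^n, n), entries +-1
    patterns = np.arange(2 ** n, dtype=np.int64)
    bits = (patterns[:, None] >> np.arange(n)) & 1
    signs = 2 * bits - 1
    w_all = signs @ ranks
    return float(np.mean(np.abs(w_all) >= abs_w - 1e-9))


@lru_cache(maxsize=32)
def exact_tail_table(n_r: int) -> np.ndarray:
    """Null distribution tail for untied ranks 1..n_r.

    Returns an array ``tail`` where ``tail[w]`` = P(|W'| >= w) for integer
    ``w`` in 0..n_r(n_r+1)/2, computed by exhaustive enumeration of the
    2^n_r sign patterns.
    """
    ranks = np.arange(1, n_r + 1, dtype=np.int64)
    patterns = np.arange(2 ** n_r, dtype=np.int64)
    bits = (patterns[:, None] >> np.arange(n_r)) & 1
    w_all = np.abs((2 * bits - 1) @ ranks)
    w_max = n_r * (n_r + 1) // 2
    counts = np.bincount(w_all, minlength=w_max + 1)
    tail = np.cumsum(counts[::-1])[::-1] / float(2 ** n_r)
    return tail


def wilcoxon_matched_pairs(case_vals, control_vals) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test of case vs control.

    Differences ``d_i = case_i - control_i``; zero differences are discarded;
    remaining |d_i| are ranked ascending with mid-rank ties and
    W = sum(sign(d_i) * R_i).  The p-value route depends on the number of
    non-zero pairs (see module docstring).
    """
    case_vals = np.asarray(case_vals, dtype=float)
    control_vals = np.asarray(control_vals, dtype=float)
    if case_vals.shape != control_vals.shape or case_vals.ndim != 1:
        raise ValueError(
            "case and control must be equal-length 1-D vectors, got shapes "
            f"{case_vals.shape} and {control_vals.shape}"
        )
    n = len(case_vals)
    if n < 1:
        raise ValueError("need at least one pair")
    d = case_vals - control_vals
    nz = d != 0.0
    n_r = int(nz.sum())
    if n_r == 0:
        return WilcoxonResult(n, 0, 0.0, 0.0, 0.0, 1.0, "degenerate")
    dd = d[nz]
    ranks = rankdata(np.abs(dd))
    w = float(np.sum(np.sign(dd) * ranks))
    sigma = _sigma_w(n_r)
    if n_r <= _EXACT_MAX_N:
        p = _exact_p_from_ranks(ranks, abs(w))
        z = 0.0
        method = "exact"
    else:
        z = max(abs(w) - 0.5, 0.0) / sigma
        p = float(_normal_p(abs(w), n_r))
        method = "normal_approx"
    return WilcoxonResult(n, n_r, w, sigma, z, min(max(p, 0.0), 1.0), method)


def windowed_wilcoxon(case_vals, control_vals, window: int):
    """Signed-rank p-values over all sliding windows of ``window`` pairs.

    Vectorized over windows.  Returns ``(p, w, n_r)`` arrays of length
    ``n - window + 1``; window ``i`` spans pairs ``i .. i+window-1``.

    Windows whose non-zero-difference count falls in the exact-enumeration
    regime, or that contain tied non-zero |d|, are delegated to
    :func:`wilcoxon_matched_pairs` row by row; with continuous coverage data
    both are rare unless the window itself is small.
    """
    case_vals = np.asarray(case_vals, dtype=float)
    control_vals = np.asarray(control_vals, dtype=float)
    d = case_vals - control_vals
    n = len(d)
    if window < 2 or n < window:
        return (np.empty(0), np.empty(0), np.empty(0, dtype=int))
    wins = sliding_window_view(d, window)  # (m, window) view
    absd = np.abs(wins)
    zero = absd == 0.0
    n_zero = zero.sum(axis=1)
    n_r = window - n_zero
    # Rank everything; zeros occupy the lowest ranks, so subtracting the
    # per-row zero count leaves correct mid-ranks for the non-zero entries.
    ranks = rankdata(absd, axis=1) - n_zero[:, None]
    w = np.sum(np.sign(wins) * np.where(zero, 0.0, ranks), axis=1)
    abs_w = np.abs(w)

    p = np.ones(len(wins))
    # mid-ranks from rankdata are already correct for the normal route;
    # only the exact-table lookup assumes untied ranks 1..N_r
    normal_rows = n_r > _EXACT_MAX_N
    if np.any(normal_rows):
        p[normal_rows] = _normal_p(abs_w[normal_rows], n_r[normal_rows])

    small = (n_r > 0) & (n_r <= _EXACT_MAX_N)
    if np.any(small):
        srt = np.sort(absd[small], axis=1)
        tie_small = np.any((np.diff(srt, axis=1) == 0.0)
                           & (srt[:, :-1] > 0.0), axis=1)
        small_idx = np.nonzero(small)[0]
        exact_rows = np.zeros(len(wins), dtype=bool)
        exact_rows[small_idx[~tie_small]] = True
        for nr in np.unique(n_r[exact_rows]):
            tail = exact_tail_table(int(nr))
            rows = exact_rows & (n_r == nr)
            # untied integer |W|; round guards float noise
            idx = np.rint(abs_w[rows]).astype(int)
            p[rows] = tail[np.clip(idx, 0, len(tail) - 1)]
        for i in small_idx[tie_small]:
            p[i] = wilcoxon_matched_pairs(
                wins[i] + control_vals[i:i + window],
                control_vals[i:i + window]).p_value
    return p, w, n_r
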