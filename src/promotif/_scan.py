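"""Numba kernels for batch PWM window scoring and hit accounting.

The kernels work on padded int8 code matrices (see `_seqs`). Lookup tables are
(L, 6): columns 0-3 are per-base scores, column 4 (N) and column 5 (padding)
are -inf, so any window touching an N or running off the true sequence end
scores -inf and can never pass a finite threshold.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _score_kernel(codes, lengths, lut, out):  # pragma: no cover - exercised via wrapper
    L = lut.shape[0]
    n, wmax = out.shape
    for i in range(n):
        w = lengths[i] - L + 1
        for o in range(w):
            s = 0.0
            for j in range(L):
                s += lut[j, codes[i, o + j]]
            out[i, o] = s
        for o in range(max(w, 0), wmax):
            out[i, o] = -np.inf


def score_windows(codes: np.ndarray, lengths: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Score every window of every sequence; invalid windows are -inf.

    Returns a (n, max_len - L + 1) float64 array.
    """
    L = lut.shape[0]
    n, p = codes.shape
    w = max(p - L + 1, 0)
    out = np.empty((n, w), dtype=np.float64)
    if w > 0 and n > 0:
        _score_kernel(codes, lengths, np.ascontiguousarray(lut, dtype=np.float64), out)
    return out


@njit(cache=True)
def _score_kernel_pair(codes, lengths, lut_p, lut_m, out_p, out_m):  # pragma: no cover
    L = lut_p.shape[0]
    n, wmax = out_p.shape
    for i in range(n):
        w = lengths[i] - L + 1
        for o in range(w):
            sp = 0.0
            sm = 0.0
            for j in range(L):
                c = codes[i, o + j]
                sp += lut_p[j, c]
                sm += lut_m[j, c]
            out_p[i, o] = sp
            out_m[i, o] = sm
        for o in range(max(w, 0), wmax):
            out_p[i, o] = -np.inf
            out_m[i, o] = -np.inf


def score_windows_pair(codes: np.ndarray, lengths: np.ndarray, lut_p: np.ndarray,
                       lut_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score both strand orientations in one pass over the code matrix."""
    L = lut_p.shape[0]
    n, p = codes.shape
    w = max(p - L + 1, 0)
    out_p = np.empty((n, w), dtype=np.float64)
    out_m = np.empty((n, w), dtype=np.float64)
    if w > 0 and n > 0:
        _score_kernel_pair(codes, lengths,
                           np.ascontiguousarray(lut_p, dtype=np.float64),
                           np.ascontiguousarray(lut_m, dtype=np.float64),
                           out_p, out_m)
    return out_p, out_m


@njit(cache=True)
def _top_tail_kernel(plus, minus, k, nbins, lo, hi):  # pragma: no cover
    """All finite scores >= an automatically chosen cutoff admitting >= k+1 of
    them (or all finite scores if fewer), plus the total finite count.

    ``lo``/``hi`` bound every finite score (e.g. matrix min/max attainable
    score); -inf marks invalid windows and is the only non-finite value.
    """
    if lo >= hi:
        # degenerate score range: every finite score equals the same value
        finite_n = 0
        for arr in (plus, minus):
            f = arr.ravel()
            for i in range(f.size):
                if f[i] != -np.inf:
                    finite_n += 1
        out = np.full(finite_n, hi)
        return out, finite_n
    scale = nbins / (hi - lo)
    counts = np.zeros(nbins + 1, np.int64)
    for arr in (plus, minus):
        f = arr.ravel()
        for i in range(f.size):
            v = f[i]
            if v != -np.inf:
                counts[int((v - lo) * scale)] += 1
    finite_n = 0
    for b in range(nbins + 1):
        finite_n += counts[b]
    if finite_n == 0:
        return np.empty(0, np.float64), 0
    # walk bins from the top until >= k+1 scores are above the cutoff bin edge
    tail = 0
    cut_bin = 0
    for b in range(nbins, -1, -1):
        tail += counts[b]
        cut_bin = b
        if tail >= k + 1:
            break
    # relax by a sliver of a bin so float rounding never drops a boundary score
    cutoff = lo + (cut_bin - 0.001) / scale
    out = np.empty(tail + counts[max(cut_bin - 1, 0)] + 1, np.float64)
    j = 0
    for arr in (plus, minus):
        f = arr.ravel()
        for i in range(f.size):
            if f[i] != -np.inf and f[i] >= cutoff:
                out[j] = f[i]
                j += 1
    return out[:j], finite_n


def top_scores_pair(plus: np.ndarray, minus: np.ndarray, k: int,
                    lo: float | None = None, hi: float | None = None
                    ) -> tuple[np.ndarray, int]:
    """Descending-sorted top >= k+1 finite scores of both strands, and the
    total finite-score count (returns everything when fewer exist)."""
    if lo is None or hi is None or not (np.isfinite(lo) and np.isfinite(hi)):
        finite = np.concatenate([plus[plus != -np.inf], minus[minus != -np.inf]])
        if finite.size == 0:
            return np.empty(0), 0
        lo, hi = float(finite.min()), float(finite.max())
    vals, finite_n = _top_tail_kernel(plus, minus, int(k), 4096,
                                      float(lo), float(hi))
    vals = np.sort(vals)[::-1]
    if vals.size > k + 1:
        # keep k+1, extended through any tie at the boundary value
        edge = vals[k]
        keep = int(np.searchsorted(-vals, -edge, side="right"))
        vals = vals[:keep]
    return vals, int(finite_n)


@njit(cache=True)
def _collapse_row(row, thr, L):  # pragma: no cover
    n = 0
    for o in range(row.size):
        if row[o] >= thr:
            n += 1
    if n == 0:
        return 0
    offs = np.empty(n, np.int64)
    vals = np.empty(n, np.float64)
    j = 0
    for o in range(row.size):
        if row[o] >= thr:
            offs[j] = o
            vals[j] = row[o]
            j += 1
    order = np.argsort(-vals, kind="mergesort")  # stable: ties stay leftmost-first
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    kept = 0
    for idx in order:
        lo = offs[idx]
        hi = lo + L
        ok = True
        for t in range(kept):
            if not (hi <= starts[t] or lo >= ends[t]):
                ok = False
                break
        if ok:
            starts[kept] = lo
            ends[kept] = hi
            kept += 1
    return kept


@njit(cache=True)
def collapsed_count_pair(plus, minus, thr, L):  # pragma: no cover
    """Greedy best-score non-overlap hit count at/above thr, per promoter per strand."""
    total = 0
    for i in range(plus.shape[0]):
        total += _collapse_row(plus[i], thr, L)
        total += _collapse_row(minus[i], thr, L)
    return total
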