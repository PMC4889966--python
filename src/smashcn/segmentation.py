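"""Circular binary segmentation and integer (quantal) copy-number fitting.

CBS recursively looks for the arc of a (circularized) chromosome whose mean
differs most from the rest, accepting a split when a permutation test of the
max statistic is significant at ``alpha``.  Segment lengths are constrained
to ``min_seg_len`` bins inside the split search, and an adjacent-segment
merge pass removes over-segmentation.  Integer copy numbers come from a
scale/offset search that places length-weighted segment means onto integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .binning import BinScheme
from .normalization import RatioTrack


@dataclass
class Segment:
    chromosome: str
    start_bin: int  # global bin index, half-open
    end_bin: int
    mean: float
    n_bins: int  # number of non-missing member bins
    integer_cn: Optional[int] = None


@dataclass
class QuantalFit:
    scale: float
    offset: float
    objective: float
    low_confidence: bool = False


@njit(cache=True)
def _max_arc_stat(x, minlen):  # pragma: no cover - numba
    """Max |mean_in - mean_out| / sqrt(1/k + 1/(n-k)) over arcs [i, j).

    Arc constraints keep every resulting piece either empty or at least
    minlen bins: k in [minlen, n-minlen], i in {0} u [minlen, n), and
    j in {n} u (0, n-minlen].
    """
    n = x.size
    S = np.empty(n + 1)
    S[0] = 0.0
    for t in range(n):
        S[t + 1] = S[t] + x[t]
    total = S[n]
    best = -1.0
    bi, bj = 0, n
    for i in range(0, n - minlen + 1):
        if i != 0 and i < minlen:
            continue
        jmax = n - minlen
        for j in range(i + minlen, n + 1):
            if j != n and j > jmax:
                continue
            k = j - i
            if k > n - minlen:
                continue
            rest = n - k
            if rest == 0:
                continue
            a = S[j] - S[i]
            stat = abs(a / k - (total - a) / rest) / np.sqrt(1.0 / k + 1.0 / rest)
            if stat > best:
                best = stat
                bi, bj = i, j
    return best, bi, bj


@njit(cache=True)
def _perm_split_pvalue(x, minlen, observed, nperm, alpha, seed):  # pragma: no cover
    """Permutation p-value of the max arc statistic, with early stop as
    soon as the split can no longer reach significance."""
    np.random.seed(seed)
    xp = x.copy()
    cnt = 0
    limit = alpha * (nperm + 1) - 1.0
    for p in range(nperm):
        np.random.shuffle(xp)
        stat, _, _ = _max_arc_stat(xp, minlen)
        if stat >= observed:
            cnt += 1
            if cnt > limit:
                return (1.0 + cnt) / (2.0 + p)
    return (1.0 + cnt) / (1.0 + nperm)


@njit(cache=True)
def _perm_ttest_pvalue(a, b, nperm, alpha, seed):  # pragma: no cover - numba
    """Permutation two-sample mean test for adjacent-segment merging."""
    n1, n2 = a.size, b.size
    obs = abs(a.mean() - b.mean()) / np.sqrt(1.0 / n1 + 1.0 / n2)
    pool = np.empty(n1 + n2)
    pool[:n1] = a
    pool[n1:] = b
    np.random.seed(seed)
    cnt = 0
    limit = alpha * (nperm + 1) - 1.0
    for p in range(nperm):
        np.random.shuffle(pool)
        stat = abs(pool[:n1].mean() - pool[n1:].mean()) / np.sqrt(1.0 / n1 + 1.0 / n2)
        if stat >= obs:
            cnt += 1
            if cnt > limit:
                return (1.0 + cnt) / (2.0 + p)
    return (1.0 + cnt) / (1.0 + nperm)


def _segment_one_chrom(
    values: np.ndarray,
    alpha: float,
    min_seg_len: int,
    permutations: int,
    seed: int,
) -> List[Tuple[int, int]]:
    """Segment a chromosome's non-missing value vector; returns half-open
    (start, end) pieces in the local (non-missing) index space."""
    pieces: List[Tuple[int, int]] = []
    counter = [seed]

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_seg_len:
            pieces.append((lo, hi))
            return
        x = values[lo:hi]
        if np.ptp(x) == 0.0:
            pieces.append((lo, hi))
            return
        stat, i, j = _max_arc_stat(x, min_seg_len)
        counter[0] = (counter[0] * 1103515245 + 12345) % (2**31)
        p = _perm_split_pvalue(x, min_seg_len, stat, permutations, alpha, counter[0])
        if p > alpha:
            pieces.append((lo, hi))
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        if not cuts:
            pieces.append((lo, hi))
            return
        bounds = [0] + cuts + [n]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(lo + a, lo + b)

    recurse(0, len(values))
    pieces.sort()
    return pieces


def _merge_pass(
    values: np.ndarray,
    pieces: List[Tuple[int, int]],
    alpha: float,
    permutations: int,
    seed: int,
) -> List[Tuple[int, int]]:
    """Merge adjacent pieces whose difference is not significant; the least
    significant pair is merged first, repeatedly."""
    pieces = list(pieces)
    counter = seed
    while len(pieces) > 1:
        pvals = []
        for idx in range(len(pieces) - 1):
            a = values[pieces[idx][0] : pieces[idx][1]]
            b = values[pieces[idx + 1][0] : pieces[idx + 1][1]]
            counter = (counter * 1103515245 + 12345) % (2**31)
            pvals.append(_perm_ttest_pvalue(a, b, permutations, alpha, counter))
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            break
        lo = pieces[worst][0]
        hi = pieces[worst + 1][1]
        pieces[worst : worst + 2] = [(lo, hi)]
    return pieces


def cbs_segment(
    track: RatioTrack,
    scheme: BinScheme,
    alpha: float = 0.02,
    min_seg_len: int = 3,
    permutations: int = 10000,
    seed: int = 0,
    merge: bool = True,
) -> List[Segment]:
    """Segment a ratio track chromosome by chromosome.

    Missing bins are excluded; each chromosome's non-missing bins are
    partitioned into segments of at least min_seg_len bins (chromosomes
    shorter than that return a single segment).  Deterministic given seed.
    """
    chrom_arr = scheme.table["chrom"].to_numpy()
    segments: List[Segment] = []
    for ci, chrom in enumerate(scheme.chroms):
        sel = np.flatnonzero((chrom_arr == chrom) & ~track.missing)
        if sel.size == 0:
            continue
        values = track.values[sel]
        chrom_seed = (seed + 7919 * (ci + 1)) % (2**31)
        if sel.size < 2 * min_seg_len:
            pieces = [(0, sel.size)]
        else:
            pieces = _segment_one_chrom(values, alpha, min_seg_len, permutations, chrom_seed)
            if merge and len(pieces) > 1:
                pieces = _merge_pass(values, pieces, alpha, permutations, chrom_seed + 1)
        for lo, hi in pieces:
            member = sel[lo:hi]
            segments.append(
                Segment(
                    chromosome=chrom,
                    start_bin=int(member[0]),
                    end_bin=int(member[-1]) + 1,
                    mean=float(values[lo:hi].mean()),
                    n_bins=hi - lo,
                )
            )
    return segments


def quantal_fit(
    segments: Sequence[Segment],
    s_bounds: Tuple[float, float] = (1.0, 4.0),
    o_bounds: Tuple[float, float] = (-0.4, 0.4),
    grid_step: float = 0.01,
) -> QuantalFit:
    """Find scale s and offset o minimizing the length-weighted squared
    distance of s*mean + o to the nearest integers; assigns integer_cn to
    each segment in place.

    Ties (e.g. a flat diploid profile fits equally at s and 2s) resolve to
    the smallest scale within bounds.
    """
    if not segments:
        raise ValueError("no segments to fit")
    means = np.array([s.mean for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)

    if np.ptp(means) < 1e-9:
        # degenerate: a single level cannot identify the scale; assume the
        # genome-wide level is diploid
        s = 2.0 / means[0] if means[0] > 0 else s_bounds[0]
        s = float(np.clip(s, *s_bounds))
        fit = QuantalFit(scale=s, offset=0.0, objective=0.0, low_confidence=True)
        for seg in segments:
            seg.integer_cn = int(round(s * seg.mean))
        return fit

    def objective(s: float, o: float) -> float:
        y = s * means + o
        d = y - np.round(y)
        return float(np.sum(weights * d * d))

    s_grid = np.arange(s_bounds[0], s_bounds[1] + grid_step / 2, grid_step)
    o_grid = np.arange(o_bounds[0], o_bounds[1] + grid_step / 2, grid_step)
    y = np.outer(s_grid, means)[:, None, :] + o_grid[None, :, None]
    d = y - np.round(y)
    obj = np.einsum("sok,k->so", d * d, weights)
    flat = np.argmin(obj + 1e-12 * s_grid[:, None])  # tie-break: smallest s
    si, oi = np.unravel_index(flat, obj.shape)
    best_s, best_o = float(s_grid[si]), float(o_grid[oi])

    res = minimize(
        lambda p: objective(
            float(np.clip(p[0], *s_bounds)), float(np.clip(p[1], *o_bounds))
        ),
        x0=[best_s, best_o],
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-10},
    )
    s_fit = float(np.clip(res.x[0], *s_bounds))
    o_fit = float(np.clip(res.x[1], *o_bounds))
    if objective(s_fit, o_fit) > obj[si, oi]:
        s_fit, o_fit = best_s, best_o
    fit = QuantalFit(scale=s_fit, offset=o_fit, objective=objective(s_fit, o_fit))
    for seg in segments:
        seg.integer_cn = int(round(s_fit * seg.mean + o_fit))
    return fit


def segments_to_frame(segments: Sequence[Segment], scheme: BinScheme):
    """Segments as a BED-like DataFrame with bp coordinates."""
    import pandas as pd

    rows = []
    for s in segments:
        start_bp = int(scheme.table["start"].iloc[s.start_bin])
        end_bp = int(scheme.table["end"].iloc[s.end_bin - 1])
        rows.append(
            (s.chromosome, start_bp, end_bp, s.n_bins, s.mean, s.integer_cn)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_bins", "mean_ratio", "integer_cn"]
    )
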