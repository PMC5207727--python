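"""Windowed log2-ratio CNV profiles, circular binary segmentation, copy calls.

The log2 ratio of a window is log2(sample / control) after both samples'
GC-normalized counts are scaled to a common level.  Scaling uses the
autosomal *median* normalized count: the median keeps the 2-copy baseline
at log2 = 0 even when a large amplification inflates the mean, so absolute
copy-number calls are unbiased by the event being called.

Segmentation is canonical circular binary segmentation (CBS): for each
current segment find the arc (i, j) maximizing the pooled-sd standardized
mean difference between arc and complement; accept the split if its
permutation p-value is below alpha, recurse, then merge segments narrower
than ``min_width`` into the neighbour with the closer mean.  The circular
arc statistic is symmetric under complementation, so scanning linear arcs
covers the wrapped ones.  The permutation test stops early once enough
exceedances have accumulated to decide p > alpha ("undo splits" pruning is
deliberately omitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import WindowGrid, WindowProfile


@dataclass
class CnvProfile:
    grid: WindowGrid
    log2_ratio: np.ndarray  # per window; NaN where masked
    valid: np.ndarray  # bool per window
    sample_id: str = ""
    control_id: str = ""


@dataclass
class Segment:
    chrom: str
    start_window: int  # global window indices, half-open
    end_window: int
    start: int  # genomic bp
    end: int
    n_windows: int
    mean_log2: float
    copy_number_call: int

    @property
    def raw_copy_number(self) -> float:
        return 2.0 * 2.0**self.mean_log2


@dataclass
class SegmentSet:
    segments: list[Segment]

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        out = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.chrom == b.chrom:
                out.append((b.chrom, b.start_window))
        return out

    def overlapping(self, chrom: str, start: int, end: int) -> list[Segment]:
        return [s for s in self.segments
                if s.chrom == chrom and s.start < end and s.end > start]


def log2_ratio(sample_profile: WindowProfile, control_profile: WindowProfile,
               use_sex_chroms: bool = True) -> CnvProfile:
    """Per-window log2(sample/control) of median-scaled GC-normalized counts.

    Windows where either profile is masked, non-finite, or the control is
    zero are invalid (NaN).
    """
    grid = sample_profile.grid
    cg = control_profile.grid
    if cg.n_windows != grid.n_windows or not np.array_equal(cg.start, grid.start):
        raise ValueError("sample and control are on different window grids")
    s = sample_profile.require("gc_norm_count").astype(float)
    c = control_profile.require("gc_norm_count").astype(float)

    valid = grid.analysis_mask(use_sex_chroms)
    for p in (sample_profile, control_profile):
        if p.extreme_mask is not None:
            valid = valid & ~p.extreme_mask
    valid = valid & np.isfinite(s) & np.isfinite(c) & (c > 0)

    scale_on = valid & grid.autosomal
    s_med = np.median(s[scale_on])
    c_med = np.median(c[scale_on])
    if s_med <= 0 or c_med <= 0:
        raise ValueError("non-positive median normalized count")
    ratio = np.full(grid.n_windows, np.nan)
    ok = valid & (s > 0)
    ratio[ok] = np.log2((s[ok] / s_med) / (c[ok] / c_med))
    valid = valid & np.isfinite(ratio)
    return CnvProfile(grid, ratio, valid,
                      sample_profile.sample_id, control_profile.sample_id)


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Max over arcs [i, j) of the standardized arc-vs-complement mean
    difference; O(m^2) exhaustive scan."""
    m = x.size
    S = np.concatenate([[0.0], np.cumsum(x)])
    tot = S[-1]
    sd = x.std(ddof=0)
    if sd == 0 or m < 2:
        return 0.0, 0, 0
    i = np.arange(m + 1)
    # arc sums for all i<j via broadcasting
    arc = S[None, :] - S[:, None]  # arc[i, j] = sum x[i:j]
    n1 = (i[None, :] - i[:, None]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n2 = m - n1
        mean1 = arc / n1
        mean2 = (tot - arc) / n2
        t = (mean1 - mean2) / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    t = np.abs(t)
    t[~np.isfinite(t)] = 0.0
    t = np.triu(t, k=1)
    flat = int(np.argmax(t))
    bi, bj = divmod(flat, m + 1)
    return float(t[bi, bj]), int(bi), int(bj)


def _perm_pvalue(x: np.ndarray, obs: float, alpha: float, n_perm: int,
                 rng: np.random.Generator) -> float:
    """Sequential permutation p-value with early stopping: once the number
    of exceedances guarantees p > alpha, stop."""
    stop_at = int(np.floor(alpha * n_perm)) + 1
    exceed = 0
    for b in range(1, n_perm + 1):
        perm = rng.permutation(x)
        stat, _, _ = _max_arc_stat(perm)
        if stat >= obs:
            exceed += 1
            if exceed >= stop_at:
                return exceed / b  # already > alpha, exact value irrelevant
    return exceed / n_perm


def cbs_bounds(x: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
               min_width: int = 3,
               rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """CBS split points for one chromosome's values; returns half-open
    (start, end) index bounds partitioning ``x``."""
    if rng is None:
        rng = np.random.default_rng(0)
    bounds: list[tuple[int, int]] = []

    def split(lo: int, hi: int):
        seg = x[lo:hi]
        if hi - lo < 2 * min_width or seg.std(ddof=0) == 0:
            bounds.append((lo, hi))
            return
        stat, i, j = _max_arc_stat(seg)
        if stat == 0.0:
            bounds.append((lo, hi))
            return
        p = _perm_pvalue(seg, stat, alpha, n_perm, rng)
        if p >= alpha:
            bounds.append((lo, hi))
            return
        cuts = sorted({0, i, j, hi - lo})
        for a, b in zip(cuts, cuts[1:]):
            split(lo + a, lo + b)

    split(0, x.size)
    bounds.sort()
    return _merge_narrow(x, bounds, min_width)


def _merge_narrow(x, bounds, min_width):
    # merge narrow segments into the neighbour with the closer mean
    means = [float(x[a:b].mean()) for a, b in bounds]
    changed = True
    while changed and len(bounds) > 1:
        changed = False
        for k, (a, b) in enumerate(bounds):
            if b - a >= min_width:
                continue
            nbrs = []
            if k > 0:
                nbrs.append((abs(means[k] - means[k - 1]), k - 1))
            if k < len(bounds) - 1:
                nbrs.append((abs(means[k] - means[k + 1]), k + 1))
            _, tgt = min(nbrs)
            lo = min(bounds[k][0], bounds[tgt][0])
            hi = max(bounds[k][1], bounds[tgt][1])
            for idx in sorted((k, tgt), reverse=True):
                del bounds[idx]
                del means[idx]
            ins = k if tgt > k else tgt
            bounds.insert(ins, (lo, hi))
            means.insert(ins, float(x[lo:hi].mean()))
            changed = True
            break
    return bounds


def cbs_segment(profile: CnvProfile, alpha: float = 0.01, n_perm: int = 1000,
                min_width: int = 3, tumor_fraction: float | None = None,
                random_state: int = 0) -> SegmentSet:
    """Segment a log2-ratio profile chromosome by chromosome."""
    rng = np.random.default_rng(random_state)
    grid = profile.grid
    segments: list[Segment] = []
    for ci, chrom in enumerate(grid.genome.chrom_names):
        sel = np.flatnonzero((grid.chrom == ci) & profile.valid)
        if sel.size == 0:
            continue
        x = profile.log2_ratio[sel]
        for a, b in cbs_bounds(x, alpha, n_perm, min_width, rng):
            widx = sel[a:b]
            mean = float(x[a:b].mean())
            segments.append(Segment(
                chrom=chrom,
                start_window=int(widx[0]),
                end_window=int(widx[-1]) + 1,
                start=int(grid.start[widx[0]]),
                end=int(grid.end[widx[-1]]),
                n_windows=int(b - a),
                mean_log2=mean,
                copy_number_call=copy_number_call(mean, tumor_fraction),
            ))
    return SegmentSet(segments)


def copy_number_call(mean_log2: float, tumor_fraction: float | None = None) -> int:
    """Copy number from a segment mean: raw CN = 2 * 2**mean_log2; with a
    tumor fraction, deconvolve the diploid admixture
    (CN_tumor = (CN_raw - 2(1-tf)) / tf).  Negative results clamp to 0."""
    if not np.isfinite(mean_log2):
        raise ValueError("mean_log2 must be finite")
    raw = 2.0 * 2.0**mean_log2
    if tumor_fraction is not None and tumor_fraction > 0:
        raw = (raw - 2.0 * (1.0 - tumor_fraction)) / tumor_fraction
    return int(round(max(raw, 0.0)))
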