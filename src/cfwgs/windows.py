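"""10 kb window profiles: covered fraction, counts, GC normalization,
clustering, PCA, Spearman similarity.

Each chromosome is tiled with consecutive non-overlapping 10,000 bp windows
(trailing partial window retained for coverage fractions, excluded from the
multivariate analyses).  Fragments are assigned to the window containing
their midpoint.  GC normalization follows the shallow-WGS CNV convention:
LOESS of count on window GC over unmasked autosomal windows, each count
rescaled by median(fit)/fit(GC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.stats import spearmanr
import statsmodels.api as sm

from .coverage import DepthTrack
from .sim.fragments import Fragments
from .sim.genome import ToyGenome, is_sex_chrom

WINDOW_WIDTH = 10_000
LOESS_GC_RANGE = (0.25, 0.70)


@dataclass
class WindowGrid:
    """Window tiling of a genome with per-window GC and N fractions."""

    genome: ToyGenome
    width: int = WINDOW_WIDTH
    chrom: np.ndarray = field(init=False)  # chrom index per window
    start: np.ndarray = field(init=False)
    end: np.ndarray = field(init=False)
    gc: np.ndarray = field(init=False)
    n_frac: np.ndarray = field(init=False)

    def __post_init__(self):
        ch, st, en = [], [], []
        for ci, c in enumerate(self.genome.chrom_names):
            L = self.genome.length(c)
            starts = np.arange(0, L, self.width)
            ends = np.minimum(starts + self.width, L)
            ch.append(np.full(starts.size, ci, dtype=np.int32))
            st.append(starts)
            en.append(ends)
        self.chrom = np.concatenate(ch)
        self.start = np.concatenate(st)
        self.end = np.concatenate(en)
        gc = np.empty(self.chrom.size)
        nf = np.empty(self.chrom.size)
        for ci, c in enumerate(self.genome.chrom_names):
            m = self.chrom == ci
            s, e = self.start[m], self.end[m]
            gc[m] = self.genome.gc_fraction_many(c, s, e)
            nn = self.genome._n_cum[c]
            nf[m] = (nn[e] - nn[s]) / (e - s)
        self.gc = gc
        self.n_frac = nf

    @property
    def n_windows(self) -> int:
        return int(self.chrom.size)

    @property
    def full_width(self) -> np.ndarray:
        return (self.end - self.start) == self.width

    @property
    def autosomal(self) -> np.ndarray:
        sex = np.array([is_sex_chrom(c) for c in self.genome.chrom_names])
        return ~sex[self.chrom]

    @property
    def usable(self) -> np.ndarray:
        """Full-width windows with at least one non-N base."""
        return self.full_width & (self.n_frac < 1.0)

    def analysis_mask(self, use_sex_chroms: bool = True) -> np.ndarray:
        m = self.usable
        if not use_sex_chroms:
            m = m & self.autosomal
        return m


@dataclass
class WindowProfile:
    """Per-window vectors for one sample, aligned to one grid."""

    grid: WindowGrid
    sample_id: str
    covered_fraction: np.ndarray | None = None
    raw_count: np.ndarray | None = None
    gc_norm_count: np.ndarray | None = None
    extreme_mask: np.ndarray | None = None  # True where count above percentile
    gc_flagged: np.ndarray | None = None  # outside fitted GC range

    def require(self, attr: str) -> np.ndarray:
        v = getattr(self, attr)
        if v is None:
            raise ValueError(f"profile {self.sample_id!r} lacks {attr}")
        return v


def fraction_covered(track: DepthTrack, grid: WindowGrid) -> np.ndarray:
    """Per-window fraction of non-N positions with depth >= 1.

    All-N windows get NaN and are dropped by the analysis masks downstream.
    """
    out = np.empty(grid.n_windows)
    for ci, chrom in enumerate(grid.genome.chrom_names):
        m = grid.chrom == ci
        covered = ((track.depth[chrom] > 0) & track.non_n_mask(chrom)).astype(np.int64)
        cum_cov = np.concatenate([[0], np.cumsum(covered)])
        nn = grid.genome._n_cum[chrom]
        s, e = grid.start[m], grid.end[m]
        non_n = (e - s) - (nn[e] - nn[s])
        with np.errstate(invalid="ignore", divide="ignore"):
            out[m] = np.where(non_n > 0, (cum_cov[e] - cum_cov[s]) / non_n, np.nan)
    return out


def counts_per_window(fragments: Fragments, grid: WindowGrid) -> np.ndarray:
    """Fragment counts per window, midpoint assignment (one window each)."""
    offsets = np.zeros(len(grid.genome.chrom_names) + 1, dtype=np.int64)
    for ci, _c in enumerate(grid.genome.chrom_names):
        offsets[ci + 1] = offsets[ci] + int((grid.chrom == ci).sum())
    mid = (fragments.start + fragments.end) // 2
    widx = offsets[fragments.chrom_idx] + mid // grid.width
    return np.bincount(widx, minlength=grid.n_windows).astype(np.int64)


def window_profile(fragments: Fragments, track: DepthTrack, grid: WindowGrid,
                   span: float = 0.3) -> WindowProfile:
    """Convenience: counts + covered fraction + extreme mask + GC norm."""
    prof = WindowProfile(grid, fragments.sample_id)
    prof.covered_fraction = fraction_covered(track, grid)
    prof.raw_count = counts_per_window(fragments, grid)
    prof.extreme_mask = filter_extreme(prof)
    loess_gc_normalize(prof, grid, span=span)
    return prof


def filter_extreme(profile: WindowProfile, percentile: float = 99.9) -> np.ndarray:
    """Mask windows with raw count strictly above the given percentile
    (computed over usable windows); ties at the cutoff are retained."""
    counts = profile.require("raw_count")
    usable = profile.grid.usable
    cut = np.percentile(counts[usable], percentile)
    mask = (counts > cut) & usable
    profile.extreme_mask = mask
    return mask


def loess_gc_normalize(profile: WindowProfile, grid: WindowGrid,
                       span: float = 0.3) -> np.ndarray:
    """LOESS-normalize window counts against GC.

    Fits count ~ loess(GC) on unmasked usable autosomal windows whose GC is
    inside ``LOESS_GC_RANGE``, then sets
    ``gc_norm_count = raw_count * median(fit) / fit(GC)``.  Windows outside
    the fitted GC range keep their raw count and are flagged.  Degenerate GC
    spread (< 0.02) skips normalization with a warning flag.
    """
    counts = profile.require("raw_count").astype(float)
    mask = profile.extreme_mask
    if mask is None:
        mask = np.zeros(counts.size, dtype=bool)
    lo, hi = LOESS_GC_RANGE
    fit_on = (grid.usable & grid.autosomal & ~mask
              & (grid.gc >= lo) & (grid.gc <= hi))
    if int(fit_on.sum()) < 50:
        raise ValueError("need >= 50 unmasked windows for GC normalization")
    gc_fit = grid.gc[fit_on]
    if gc_fit.max() - gc_fit.min() < 0.02:
        import warnings

        warnings.warn(
            f"GC spread {gc_fit.max() - gc_fit.min():.3f} < 0.02; "
            "normalization skipped", stacklevel=2,
        )
        profile.gc_norm_count = counts.copy()
        profile.gc_flagged = np.zeros(counts.size, dtype=bool)
        return profile.gc_norm_count

    fitted = sm.nonparametric.lowess(counts[fit_on], gc_fit, frac=span,
                                     it=2, return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]
    fx, uniq_idx = np.unique(fx, return_index=True)
    fy = fy[uniq_idx]
    pred = np.interp(np.clip(grid.gc, fx[0], fx[-1]), fx, fy)
    ref = np.median(fy)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(pred > 0, counts * ref / pred, np.nan)
    out_of_range = (grid.gc < lo) | (grid.gc > hi) | np.isnan(grid.gc)
    norm[out_of_range] = counts[out_of_range]
    profile.gc_norm_count = norm
    profile.gc_flagged = out_of_range
    return norm


def _stack(profiles: list[WindowProfile], attr: str, use_sex_chroms: bool):
    grid = profiles[0].grid
    for p in profiles:
        if p.grid is not grid and (
            p.grid.n_windows != grid.n_windows
            or not np.array_equal(p.grid.start, grid.start)
        ):
            raise ValueError("profiles are on different window grids")
    mask = grid.analysis_mask(use_sex_chroms)
    for p in profiles:
        if p.extreme_mask is not None:
            mask = mask & ~p.extreme_mask
    X = np.vstack([p.require(attr)[mask] for p in profiles])
    finite = np.all(np.isfinite(X), axis=0)
    return X[:, finite], mask


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]

    def cut(self, k: int) -> dict[str, int]:
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def rec(node):
            if node.is_leaf():
                return self.sample_ids[node.id]
            return (f"({rec(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{rec(node.right)}:{node.dist - node.right.dist:.6g})")

        return rec(tree) + ";"


def hierarchical_cluster(profiles: list[WindowProfile],
                         use_sex_chroms: bool = True) -> ClusterResult:
    """Ward.D2 linkage on Euclidean distances between covered-fraction
    vectors (scipy's 'ward' on raw observations is Ward.D2)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    X, _ = _stack(profiles, "covered_fraction", use_sex_chroms)
    Z = linkage(X, method="ward")
    return ClusterResult(Z, [p.sample_id for p in profiles])


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # windows x components, orthonormal columns
    explained_variance: np.ndarray
    sample_ids: list[str]


def pca_unscaled(profiles: list[WindowProfile],
                 use_sex_chroms: bool = True) -> PcaResult:
    """Centered, *unscaled* PCA of covered-fraction vectors (the features
    are already commensurate: fractions in [0, 1])."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for PCA")
    X, _ = _stack(profiles, "covered_fraction", use_sex_chroms)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    ev = S**2 / (X.shape[0] - 1)
    return PcaResult(scores, Vt.T, ev, [p.sample_id for p in profiles])


def spearman_matrix(profiles: list[WindowProfile],
                    use_sex_chroms: bool = False) -> np.ndarray:
    """Pairwise Spearman correlation of GC-normalized window counts, sex
    chromosomes and extreme windows removed by default."""
    X, _ = _stack(profiles, "gc_norm_count", use_sex_chroms)
    n = X.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(X[i]) == 0 or np.ptp(X[j]) == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            rho = spearmanr(X[i], X[j]).statistic
            out[i, j] = out[j, i] = rho
    return out
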