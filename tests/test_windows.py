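import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from cfwgs.coverage import depth_vector
from cfwgs.sim import Fragments, make_genome
from cfwgs.windows import (
    WindowGrid,
    WindowProfile,
    counts_per_window,
    filter_extreme,
    fraction_covered,
    hierarchical_cluster,
    loess_gc_normalize,
    pca_unscaled,
    spearman_matrix,
    window_profile,
)


def toy_frags(intervals, chrom_names=("chr1",)):
    intervals = list(intervals)
    return Fragments(
        np.array([c for c, _s, _e in intervals], dtype=np.int32),
        np.array([s for _c, s, _e in intervals], dtype=np.int64),
        np.array([e for _c, _s, e in intervals], dtype=np.int64),
        list(chrom_names), "t",
    )


@pytest.fixture(scope="module")
def grid100():
    g = make_genome(1, 1_000_000, ("sine", 0.30, 0.65, 200_000), seed=0)
    return WindowGrid(g)


def test_window_tiling_is_exact(grid100):
    assert grid100.n_windows == 100
    assert int((grid100.end - grid100.start).sum()) == 1_000_000
    assert np.all(np.diff(grid100.start) == 10_000)


def test_fraction_covered_toy(grid100):
    fr = toy_frags([(0, 0, 2500)])
    track = depth_vector(fr, grid100.genome)
    fc = fraction_covered(track, grid100)
    assert fc[0] == pytest.approx(0.25)
    assert np.all(fc[1:] == 0.0)


def test_counts_midpoint_rule_and_conservation(grid100):
    fr = toy_frags([(0, 9_990, 10_157), (0, 0, 100), (0, 25_000, 25_167)])
    counts = counts_per_window(fr, grid100)
    assert counts[1] == 1  # midpoint 10073 falls in window 1
    assert counts[0] == 1
    assert counts[2] == 1
    assert counts.sum() == 3


def test_uniform_counts_are_multinomial(grid100):
    rng = np.random.default_rng(4)
    n = 100_000
    s = rng.integers(0, 999_800, size=n)
    fr = toy_frags(zip(np.zeros(n, dtype=int), s.tolist(), (s + 150).tolist()))
    counts = counts_per_window(fr, grid100)
    assert chisquare(counts).pvalue > 0.01


def test_filter_extreme_percentile():
    g = make_genome(1, 10_000_000, ("uniform", 0.5), seed=1)
    grid = WindowGrid(g)
    prof = WindowProfile(grid, "s")
    prof.raw_count = np.arange(1, grid.n_windows + 1, dtype=np.int64)
    mask = filter_extreme(prof)
    assert mask.sum() == 1 and mask[-1]  # only the single top window
    assert mask.mean() <= 0.002

    prof2 = WindowProfile(grid, "s2")
    prof2.raw_count = np.full(grid.n_windows, 7, dtype=np.int64)
    assert filter_extreme(prof2).sum() == 0  # all tie at the cutoff


def test_loess_is_scale_equivariant(flat_run):
    _scene, grid, _neutral, biased = flat_run
    p1 = WindowProfile(grid, "a")
    p1.raw_count = counts_per_window(biased, grid)
    filter_extreme(p1)
    loess_gc_normalize(p1, grid)
    p2 = WindowProfile(grid, "b")
    p2.raw_count = p1.raw_count * 2
    p2.extreme_mask = p1.extreme_mask
    loess_gc_normalize(p2, grid)
    m = grid.usable & ~p1.extreme_mask
    assert np.allclose(p2.gc_norm_count[m], 2 * p1.gc_norm_count[m],
                       rtol=1e-9)


def test_loess_no_bias_leaves_counts_almost_unchanged(flat_run):
    _scene, grid, neutral, _biased = flat_run
    prof = WindowProfile(grid, "n")
    prof.raw_count = counts_per_window(neutral, grid)
    filter_extreme(prof)
    loess_gc_normalize(prof, grid)
    m = grid.usable & ~prof.extreme_mask & (prof.raw_count > 0)
    rel = np.abs(prof.gc_norm_count[m] / prof.raw_count[m] - 1.0)
    assert np.median(rel) < 0.02


def test_loess_removes_planted_gc_bias(flat_run):
    _scene, grid, _neutral, biased = flat_run
    prof = WindowProfile(grid, "b")
    prof.raw_count = counts_per_window(biased, grid)
    filter_extreme(prof)
    loess_gc_normalize(prof, grid)
    m = grid.usable & ~prof.extreme_mask
    pre = spearmanr(prof.raw_count[m], grid.gc[m]).statistic
    post = spearmanr(prof.gc_norm_count[m], grid.gc[m]).statistic
    assert abs(pre) > 0.3
    assert abs(post) < 0.05
    assert abs(post) < abs(pre)


def test_gc_neutral_sample_shows_no_count_gc_correlation(flat_run):
    _scene, grid, neutral, _biased = flat_run
    counts = counts_per_window(neutral, grid)
    m = grid.usable
    assert m.sum() >= 200
    rho = spearmanr(counts[m], grid.gc[m]).statistic
    assert abs(rho) < 0.05


def _profiles_for(grid, frag_sets, ids):
    out = []
    for fr, sid in zip(frag_sets, ids):
        fr.sample_id = sid
        track = depth_vector(fr, grid.genome)
        prof = WindowProfile(grid, sid)
        prof.covered_fraction = fraction_covered(track, grid)
        prof.raw_count = counts_per_window(fr, grid)
        out.append(prof)
    return out


def test_identical_profiles_merge_first(grid100):
    rng = np.random.default_rng(5)
    s = rng.integers(0, 999_800, size=5_000)
    ivs = list(zip(np.zeros(5_000, dtype=int), s.tolist(), (s + 150).tolist()))
    a, b = toy_frags(ivs), toy_frags(ivs)
    rng2 = np.random.default_rng(6)
    s2 = rng2.integers(0, 999_800, size=5_000)
    c = toy_frags(zip(np.zeros(5_000, dtype=int), s2.tolist(), (s2 + 150).tolist()))
    profs = _profiles_for(grid100, [a, b, c], ["a", "b", "c"])
    res = hierarchical_cluster(profs)
    first = res.linkage_matrix[0]
    assert {int(first[0]), int(first[1])} == {0, 1}
    assert first[2] == 0.0


def test_mismatched_grids_rejected(grid100):
    g2 = make_genome(1, 500_000, ("uniform", 0.5), seed=2)
    grid2 = WindowGrid(g2)
    p1 = WindowProfile(grid100, "a")
    p1.covered_fraction = np.zeros(grid100.n_windows)
    p2 = WindowProfile(grid2, "b")
    p2.covered_fraction = np.zeros(grid2.n_windows)
    with pytest.raises(ValueError, match="grid"):
        hierarchical_cluster([p1, p2])


def test_pca_duplicates_coincide_and_loadings_orthonormal(grid100):
    rng = np.random.default_rng(7)
    sets = []
    for k in range(3):
        s = rng.integers(0, 999_800, size=5_000)
        sets.append(toy_frags(zip(np.zeros(5_000, dtype=int), s.tolist(),
                                  (s + 150).tolist())))
    sets.append(sets[0].subset(np.ones(5_000, dtype=bool)))  # duplicate of 0
    profs = _profiles_for(grid100, sets, ["a", "b", "c", "a2"])
    res = pca_unscaled(profs)
    assert np.allclose(res.scores[0], res.scores[3], atol=1e-9)
    gram = res.loadings.T @ res.loadings
    assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
    # total variance is conserved by the rotation
    X = np.vstack([p.covered_fraction for p in profs])
    total = ((X - X.mean(0)) ** 2).sum() / (X.shape[0] - 1)
    assert np.isclose(res.explained_variance.sum(), total, rtol=1e-9)


def test_spearman_trivial_values(grid100):
    p1 = WindowProfile(grid100, "a")
    p1.gc_norm_count = np.linspace(1, 50, grid100.n_windows)
    p2 = WindowProfile(grid100, "b")
    p2.gc_norm_count = p1.gc_norm_count.copy()
    p3 = WindowProfile(grid100, "c")
    p3.gc_norm_count = np.exp(p1.gc_norm_count / 10.0)  # monotone transform
    rho = spearman_matrix([p1, p2, p3], use_sex_chroms=True)
    assert rho[0, 1] == pytest.approx(1.0)
    assert rho[0, 2] == pytest.approx(1.0)
    assert np.allclose(rho, rho.T)
    assert np.all(np.diag(rho) == 1.0)
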