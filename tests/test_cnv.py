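import numpy as np
import pytest

from cfwgs.cnv import (
    CnvProfile,
    _max_arc_stat,
    cbs_bounds,
    cbs_segment,
    copy_number_call,
    log2_ratio,
)
from cfwgs.sim import make_genome
from cfwgs.windows import WindowGrid, WindowProfile


@pytest.fixture(scope="module")
def grid250():
    g = make_genome(1, 250 * 10_000, ("uniform", 0.5), seed=0)
    return WindowGrid(g)


def profile_from(grid, values, sid="s"):
    p = WindowProfile(grid, sid)
    p.gc_norm_count = np.asarray(values, dtype=float)
    return p


def test_log2_ratio_doubled_windows(grid250):
    control = np.full(grid250.n_windows, 2.0)
    sample = control.copy()
    sample[50:60] = 4.0  # scattered gain; medians stay at 2
    prof = log2_ratio(profile_from(grid250, sample),
                      profile_from(grid250, control))
    assert np.allclose(prof.log2_ratio[50:60], 1.0)
    assert np.allclose(prof.log2_ratio[:50], 0.0)


def test_log2_ratio_identical_profiles_zero(grid250):
    v = np.random.default_rng(0).uniform(50, 150, grid250.n_windows)
    prof = log2_ratio(profile_from(grid250, v), profile_from(grid250, v))
    assert np.allclose(prof.log2_ratio[prof.valid], 0.0)


def test_log2_ratio_grid_mismatch_rejected(grid250):
    g2 = make_genome(1, 100 * 10_000, ("uniform", 0.5), seed=1)
    other = WindowGrid(g2)
    with pytest.raises(ValueError, match="grid"):
        log2_ratio(profile_from(grid250, np.ones(grid250.n_windows)),
                   profile_from(other, np.ones(other.n_windows)))


def test_control_zero_windows_masked(grid250):
    control = np.full(grid250.n_windows, 2.0)
    control[10] = 0.0
    prof = log2_ratio(profile_from(grid250, control * 1.0),
                      profile_from(grid250, control))
    assert not prof.valid[10]
    assert np.isnan(prof.log2_ratio[10])


def test_noiseless_piecewise_constant_breakpoints_exact(grid250):
    x = np.zeros(250)
    x[100:150] = 1.0
    prof = CnvProfile(grid250, x, np.ones(250, dtype=bool))
    segs = cbs_segment(prof)
    assert [(s.start_window, s.end_window) for s in segs.segments] == [
        (0, 100), (100, 150), (150, 250)
    ]


def test_single_split_matches_exhaustive_oracle():
    rng = np.random.default_rng(8)
    for _ in range(5):
        x = rng.normal(0, 1, size=60)
        stat, i, j = _max_arc_stat(x)
        # brute-force all arcs
        best = (0.0, 0, 0)
        S = np.concatenate([[0.0], np.cumsum(x)])
        sd = x.std()
        m = x.size
        for a in range(m):
            for b in range(a + 1, m + 1):
                n1 = b - a
                n2 = m - n1
                if n2 == 0:
                    continue
                t = abs((S[b] - S[a]) / n1 - (S[m] - S[b] + S[a]) / n2) / (
                    sd * np.sqrt(1 / n1 + 1 / n2)
                )
                if t > best[0]:
                    best = (t, a, b)
        assert (i, j) == (best[1], best[2])
        assert stat == pytest.approx(best[0])


def test_false_positive_rate_on_flat_noisy_profiles():
    n_single = 0
    runs = 100
    for seed in range(runs):
        rng = np.random.default_rng(1000 + seed)
        x = rng.normal(0.0, 0.1, size=100)
        bounds = cbs_bounds(x, alpha=0.01, n_perm=1000, min_width=3,
                            rng=np.random.default_rng(seed))
        if len(bounds) == 1:
            n_single += 1
    assert n_single >= 95


def test_more_permissive_alpha_never_fewer_segments_on_average():
    totals = {0.001: 0, 0.05: 0}
    for seed in range(8):
        rng = np.random.default_rng(50 + seed)
        x = np.concatenate([
            rng.normal(0, 0.25, 60), rng.normal(0.5, 0.25, 40),
            rng.normal(-0.3, 0.25, 60),
        ])
        for alpha in totals:
            totals[alpha] += len(cbs_bounds(
                x, alpha=alpha, n_perm=500, rng=np.random.default_rng(seed)))
    assert totals[0.05] >= totals[0.001]


def test_segment_means_conserve_global_mean(grid250):
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(1.2, 0.1, 50),
                        rng.normal(0, 0.1, 100)])
    prof = CnvProfile(grid250, x, np.ones(250, dtype=bool))
    segs = cbs_segment(prof)
    weighted = sum(s.mean_log2 * s.n_windows for s in segs.segments)
    n = sum(s.n_windows for s in segs.segments)
    assert weighted / n == pytest.approx(x.mean())


def test_copy_number_call_algebra():
    assert copy_number_call(0.0) == 2
    assert copy_number_call(np.log2(10.0)) == 20
    # tf deconvolution: raw CN 4 at tf=0.5 implies tumor CN 6
    assert copy_number_call(1.0, tumor_fraction=0.5) == 6
    # negative implied CN clamps to zero
    assert copy_number_call(-8.0, tumor_fraction=0.1) == 0
    with pytest.raises(ValueError):
        copy_number_call(float("nan"))


def test_short_chromosome_single_segment(grid250):
    x = np.zeros(250)
    x[:4] = 5.0
    prof = CnvProfile(grid250, x[:5], np.ones(5, dtype=bool))
    # fewer than 2*min_width windows -> no split attempted
    segs = cbs_segment(CnvProfile(grid250, np.zeros(250),
                                  np.r_[np.ones(5, bool), np.zeros(245, bool)]))
    assert len(segs.segments) == 1
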