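import numpy as np
import pytest
from scipy.stats import chisquare

from cfwgs.io import write_fragments
from cfwgs.sim import (
    CnvSpec,
    FeatureAnnotation,
    NUCLEOSOME_SPAN,
    SamplingConfig,
    make_genome,
    place_nucleosomes,
    simulate_cfdna_fragments,
    simulate_sheared_fragments,
)


@pytest.fixture(scope="module")
def flat_small():
    """Gene-free 1 Mb diploid chromosome: all dyads are full-span background."""
    g = make_genome(1, 1_000_000, ("uniform", 0.5), seed=0)
    nmap = place_nucleosomes(g, None, seed=1)
    return g, nmap


def test_degenerate_trimming_gives_constant_length(flat_small):
    g, nmap = flat_small
    cfg = SamplingConfig(
        n_fragments=2000, seed=3, trim_geometric_p=1.0,
        dinucleosome_fraction=0.0, phased_fraction=1.0, gc_bias_strength=0.0,
    )
    frags = simulate_cfdna_fragments(g, nmap, None, cfg)
    assert np.all(frags.lengths == NUCLEOSOME_SPAN)


def test_fragment_count_conservation(flat_small):
    g, nmap = flat_small
    cfg = SamplingConfig(n_fragments=12_345, seed=4)
    frags = simulate_cfdna_fragments(g, nmap, None, cfg)
    assert len(frags) == 12_345


def test_identical_seed_byte_identical_output(flat_small, tmp_path):
    g, nmap = flat_small
    cfg = SamplingConfig(n_fragments=5000, seed=11)
    p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
    write_fragments(simulate_cfdna_fragments(g, nmap, None, cfg), p1)
    write_fragments(simulate_cfdna_fragments(g, nmap, None, cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_midpoints_uniform_over_dyads_without_bias(flat_small):
    g, nmap = flat_small
    cfg = SamplingConfig(
        n_fragments=100_000, seed=5, gc_bias_strength=0.0,
        phased_fraction=1.0, dinucleosome_fraction=0.0, trim_geometric_p=1.0,
    )
    frags = simulate_cfdna_fragments(g, nmap, None, cfg)
    mids = ((frags.start + frags.end) // 2).astype(np.int64)
    dyads = nmap.pos["chr1"]
    idx = np.clip(np.searchsorted(dyads, mids), 0, dyads.size - 1)
    left = np.clip(idx - 1, 0, None)
    nearest = np.where(
        np.abs(dyads[idx] - mids) <= np.abs(dyads[left] - mids), idx, left
    )
    counts = np.bincount(nearest, minlength=dyads.size)
    p = chisquare(counts).pvalue
    assert p > 0.01


def test_copy_number_linearity(flat_small):
    g, nmap = flat_small
    cnv = CnvSpec(segments=(("chr1", 0, 500_000, 6),), tumor_fraction=1.0)
    cfg = SamplingConfig(n_fragments=100_000, seed=6, gc_bias_strength=0.0)
    frags = simulate_cfdna_fragments(g, nmap, cnv, cfg)
    mids = (frags.start + frags.end) // 2
    k = int((mids < 500_000).sum())
    n = len(frags)
    # expected fraction p = 3/(3+1) up to the dyad split between halves
    d = nmap.pos["chr1"]
    w = np.where(d < 500_000, 3.0, 1.0)
    p_exp = w[d < 500_000].sum() / w.sum()
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(k / n - p_exp) < 3 * se
    ratio = (k / 500_000) / ((n - k) / 500_000)
    assert abs(ratio - 3.0) < 0.15


def test_fragments_avoid_gaps_and_private_deletions():
    g = make_genome(1, 500_000, ("uniform", 0.5),
                    n_gap_spec={"chr1": [(200_000, 210_000)]}, seed=2)
    nmap = place_nucleosomes(g, None, seed=3)
    dels = (("chr1", 300_000, 302_000),)
    cfg = SamplingConfig(n_fragments=30_000, seed=7, private_deletions=dels)
    frags = simulate_cfdna_fragments(g, nmap, None, cfg)
    for lo, hi in [(200_000, 210_000), (300_000, 302_000)]:
        assert not ((frags.start < hi) & (frags.end > lo)).any()


def test_sheared_lengths_follow_normal_law(flat_small):
    g, _ = flat_small
    cfg = SamplingConfig(n_fragments=50_000, sample_type="blood_gdna", seed=8,
                         gc_bias_strength=0.0)
    frags = simulate_sheared_fragments(g, None, cfg)
    m = frags.lengths.mean()
    assert abs(m - 350.0) < 3 * 35.0 / np.sqrt(len(frags))
    assert frags.lengths.min() >= 50
    assert frags.lengths.max() <= 700


def test_sheared_blood_respects_private_deletions(flat_small):
    g, _ = flat_small
    dels = (("chr1", 400_000, 403_000),)
    cfg = SamplingConfig(n_fragments=30_000, sample_type="blood_gdna", seed=9,
                         private_deletions=dels)
    frags = simulate_sheared_fragments(g, None, cfg)
    assert not ((frags.start < 403_000) & (frags.end > 400_000)).any()


def test_zero_copy_segment_yields_zero_fragments(flat_small):
    g, _ = flat_small
    cnv = CnvSpec(segments=(("chr1", 100_000, 200_000, 0),), tumor_fraction=1.0)
    cfg = SamplingConfig(n_fragments=30_000, sample_type="tumor_gdna", seed=10,
                         gc_bias_strength=0.0)
    frags = simulate_sheared_fragments(g, cnv, cfg)
    mids = (frags.start + frags.end) // 2
    assert not ((mids >= 100_000) & (mids < 200_000)).any()


def test_effusion_mode_has_dinucleosomal_component(flat_small):
    g, nmap = flat_small
    cfg = SamplingConfig.preset("effusion_cfdna", 20_000, seed=12)
    frags = simulate_cfdna_fragments(g, nmap, None, cfg)
    frac_long = (frags.lengths > 250).mean()
    assert 0.1 < frac_long < 0.3  # ~dinucleosome_fraction = 0.2


def test_bad_inputs_rejected(flat_small):
    g, nmap = flat_small
    with pytest.raises(ValueError, match="n_fragments"):
        simulate_cfdna_fragments(g, nmap, None, SamplingConfig(n_fragments=0))
    empty = place_nucleosomes(
        make_genome(1, 1000, ("uniform", 0.5), seed=0), None,
        background_spacing=5000, seed=0,
    )
    if empty.n_dyads == 0:
        with pytest.raises(ValueError, match="empty"):
            simulate_cfdna_fragments(g, empty, None,
                                     SamplingConfig(n_fragments=10))
    with pytest.raises(ValueError):
        SamplingConfig(n_fragments=10, trim_geometric_p=0.0)
    with pytest.raises(ValueError):
        SamplingConfig(n_fragments=10, min_frag_len=200)
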