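import numpy as np
import pytest

from cfwgs.footprints import (
    boundary_profile,
    call_footprints,
    combined_peaks,
    depth_profile,
)
from cfwgs.sim import (
    Anchor,
    Fragments,
    SamplingConfig,
    make_annotation,
    make_genome,
    place_nucleosomes,
    simulate_cfdna_fragments,
    simulate_sheared_fragments,
)


def one_frag(chrom_names, ci, s, e):
    return Fragments(np.array([ci], dtype=np.int32), np.array([s]),
                     np.array([e]), list(chrom_names), "t")


def test_plus_strand_boundary_window_arithmetic():
    t = 5_000
    fr = one_frag(["chr1"], 0, t - 10, t + 157)
    prof = boundary_profile(fr, [Anchor("chr1", t, "+")], flank=1000)
    ws = prof.window_starts
    assert prof.count_5p[np.flatnonzero(ws == -10)[0]] == 1
    # 3' boundary is the last covered base e-1 = t+156 -> window [155, 160)
    assert prof.count_3p[np.flatnonzero(ws == 155)[0]] == 1
    assert prof.count_5p.sum() == 1 and prof.count_3p.sum() == 1


def test_minus_strand_boundary_window_arithmetic():
    t = 5_000
    fr = one_frag(["chr1"], 0, t - 156, t + 11)
    prof = boundary_profile(fr, [Anchor("chr1", t, "-")], flank=1000)
    ws = prof.window_starts
    # gene-oriented 5' boundary is genomic end-1 = t+10 -> relative -10
    assert prof.count_5p[np.flatnonzero(ws == -10)[0]] == 1
    # 3' boundary is genomic start = t-156 -> relative +156 -> window [155,160)
    assert prof.count_3p[np.flatnonzero(ws == 155)[0]] == 1


def test_boundary_count_conservation_against_brute_force(tss_run):
    scene, _cfg, frags = tss_run
    anchors = scene.annotation.tss
    prof = boundary_profile(frags, anchors, flank=1000)
    # brute force: per anchor, count gene-oriented 5' boundaries in range
    total = 0
    for a in anchors:
        m = frags.chrom_idx == frags.chrom_names.index(a.chrom)
        if a.strand == "+":
            rel = frags.start[m] - a.pos
        else:
            rel = a.pos - (frags.end[m] - 1)
        total += int(((rel >= -1000) & (rel < 1000)).sum())
    assert int(prof.count_5p.sum()) == total
    assert float(prof.freq_5p.sum()) * prof.n_anchors == pytest.approx(total)


def test_anchors_deduplicated_and_sex_excluded():
    fr = one_frag(["chr1", "chrX"], 0, 100, 267)
    anchors = [Anchor("chr1", 5000, "+"), Anchor("chr1", 5000, "+"),
               Anchor("chrX", 5000, "+")]
    prof = boundary_profile(fr, anchors, flank=1000)
    assert prof.n_anchors == 1
    with pytest.raises(ValueError, match="strand"):
        boundary_profile(fr, [Anchor("chr1", 5000, ".")], flank=1000)


def mirror_scene(strand_mix, seed=4):
    g = make_genome(1, 400_000, ("uniform", 0.5), seed=seed)
    ann = make_annotation(g, n_genes=40, exons_per_gene=2,
                          strand_mix=strand_mix, seed=seed)
    nmap = place_nucleosomes(g, ann, seed=seed)
    return g, ann, nmap


def test_strand_symmetry_of_boundary_profiles():
    """All-minus genes give the same gene-oriented profiles as all-plus."""
    profs = {}
    for mix in (0.0, 1.0):
        g, ann, nmap = mirror_scene(mix)
        cfg = SamplingConfig.preset("plasma_cfdna", 150_000, seed=13,
                                    phased_fraction=0.5)
        fr = simulate_cfdna_fragments(g, nmap, None, cfg)
        profs[mix] = boundary_profile(fr, ann.tss, flank=1000)
    n = profs[0.0].n_anchors
    # rebin to 10 bp: the even protected span cannot centre symmetrically,
    # so mirrored boundaries may land one base (one 5 bp window) apart
    c_plus = (profs[0.0].freq_5p * n).reshape(-1, 2).sum(axis=1)
    c_minus = (profs[1.0].freq_5p * n).reshape(-1, 2).sum(axis=1)
    sd = np.sqrt(c_plus + c_minus + 1.0)
    frac_ok = np.mean(np.abs(c_plus - c_minus) <= 4 * sd)
    assert frac_ok > 0.97


def test_depth_profile_mean_is_one(tss_run):
    scene, _cfg, frags = tss_run
    dp = depth_profile(frags, scene.annotation.tss, scene.genome, flank=1000,
                       anchor_class="TSS")
    assert dp.norm_depth.mean() == pytest.approx(1.0, abs=1e-9)
    assert np.all((dp.gc >= 0) & (dp.gc <= 1))


def test_sheared_gdna_profile_flat_with_no_footprints(tss_run):
    scene, _cfg, _ = tss_run
    cfg = SamplingConfig.preset("blood_gdna", 150_000, seed=14,
                                gc_bias_strength=0.0)
    fr = simulate_sheared_fragments(scene.genome, None, cfg)
    bp = boundary_profile(fr, scene.annotation.tss, flank=1000)
    calls = call_footprints(bp)
    assert calls.n_upstream + calls.n_downstream <= 1
    dp = depth_profile(fr, scene.annotation.tss, scene.genome, flank=1000)
    assert np.all(np.abs(dp.norm_depth - 1.0) < 0.15)


def test_gc_biased_gdna_depth_anticorrelates_with_gc():
    """On a genome with CpG-island-like promoters, GC-biased sheared gDNA
    under-covers the GC-rich TSS: metagene depth anticorrelates with GC."""
    from scipy.stats import spearmanr

    from cfwgs.sim import promoter_gc_scene

    scene = promoter_gc_scene(6, n_genes=100)
    cfg = SamplingConfig.preset("blood_gdna", 150_000, seed=15,
                                gc_bias_strength=6.0)
    fr = simulate_sheared_fragments(scene.genome, None, cfg)
    dp = depth_profile(fr, scene.annotation.tss, scene.genome, flank=1000)
    # smooth both tracks to the fragment scale before correlating
    k = np.ones(151) / 151
    d = np.convolve(dp.norm_depth, k, mode="valid")
    g = np.convolve(dp.gc, k, mode="valid")
    assert spearmanr(d, g).statistic < 0


def test_anchor_subsampling_stability(tss_run):
    scene, _cfg, frags = tss_run
    anchors = scene.annotation.tss
    full = boundary_profile(frags, anchors, flank=1000)
    half = boundary_profile(frags, anchors[::2], flank=1000)
    c_full = full.freq_5p * half.n_anchors  # expected counts at half size
    c_half = half.count_5p
    sd = np.sqrt(c_full + 1.0)
    assert np.mean(np.abs(c_half - c_full) <= 4 * sd) > 0.98


def test_tss_footprint_calls_recover_planted_architecture(tss_run):
    scene, _cfg, frags = tss_run
    bp = boundary_profile(frags, scene.annotation.tss, flank=1000,
                          anchor_class="TSS")
    calls = call_footprints(bp)
    assert calls.n_upstream == 4
    assert calls.n_downstream == 5
    assert 170 <= calls.spacing_median <= 190


def test_ess_profile_has_four_sharp_peaks_in_core(ess_run):
    scene, _cfg, frags = ess_run
    anchors = scene.annotation.interior_ess()
    assert len(anchors) == 300
    bp = boundary_profile(frags, anchors, flank=500, anchor_class="ESS")
    pk = combined_peaks(bp)
    core = pk[np.abs(pk) <= 200]
    assert core.size == 4
    # sub-mononucleosomal spacing in the core
    assert np.median(np.diff(np.sort(core))) < 167
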