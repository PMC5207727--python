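"""Shared desk-scale simulation fixtures (session-scoped: each heavy scene
is simulated once and reused across test modules)."""

from __future__ import annotations

import numpy as np
import pytest

from cfwgs.coverage import depth_vector
from cfwgs.sim import (
    SamplingConfig,
    ess_scene,
    flat_scene,
    simulate_cfdna_fragments,
    simulate_cohort,
    spectrum_scene,
    tss_scene,
)
from cfwgs.windows import WindowGrid, window_profile


@pytest.fixture(scope="session")
def spectrum_run():
    """1e5 plasma-mode fragments on the sparse-gene 1 Mb scene."""
    scene = spectrum_scene(1)
    cfg = SamplingConfig.preset("plasma_cfdna", 100_000, seed=7)
    frags = simulate_cfdna_fragments(scene.genome, scene.nucleosomes, None, cfg)
    return scene, cfg, frags


@pytest.fixture(scope="session")
def effusion_run(spectrum_run):
    scene, _cfg, _ = spectrum_run
    cfg = SamplingConfig.preset("effusion_cfdna", 100_000, seed=7)
    frags = simulate_cfdna_fragments(scene.genome, scene.nucleosomes, None, cfg)
    return scene, cfg, frags


@pytest.fixture(scope="session")
def tss_run():
    """2e5 plasma fragments over 200 synthetic TSS."""
    scene = tss_scene(2)
    cfg = SamplingConfig.preset("plasma_cfdna", 200_000, seed=11)
    frags = simulate_cfdna_fragments(scene.genome, scene.nucleosomes, None, cfg)
    return scene, cfg, frags


@pytest.fixture(scope="session")
def ess_run():
    """2e5 plasma fragments over 100 four-exon genes (300 interior ESS)."""
    scene = ess_scene(3)
    cfg = SamplingConfig.preset("plasma_cfdna", 200_000, seed=21)
    frags = simulate_cfdna_fragments(scene.genome, scene.nucleosomes, None, cfg)
    return scene, cfg, frags


@pytest.fixture(scope="session")
def flat_run():
    """3000-window flat diploid scene with two cfDNA samples: one GC-neutral,
    one with a strong planted GC bias."""
    scene = flat_scene(5)
    grid = WindowGrid(scene.genome)
    neutral = simulate_cfdna_fragments(
        scene.genome, scene.nucleosomes, None,
        SamplingConfig.preset("plasma_cfdna", 100_000, seed=42,
                              gc_bias_strength=0.0),
    )
    biased = simulate_cfdna_fragments(
        scene.genome, scene.nucleosomes, None,
        SamplingConfig.preset("plasma_cfdna", 100_000, seed=43,
                              gc_bias_strength=3.0),
    )
    return scene, grid, neutral, biased


@pytest.fixture(scope="session")
def cohort_run():
    """3 patients x (blood, tumor, cfDNA at tf=0.5), 1e5 fragments each,
    with window profiles."""
    scene, patients, samples = simulate_cohort(
        n_patients=3, n_fragments=100_000, seed=9
    )
    grid = WindowGrid(scene.genome)
    profiles = []
    for s in samples:
        track = depth_vector(s.fragments, scene.genome)
        profiles.append(window_profile(s.fragments, track, grid))
    return scene, patients, samples, grid, profiles
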