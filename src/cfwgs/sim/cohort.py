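"""Packaged study scenes: desk-scale genomes, patients and sample sets.

These builders pin down the synthetic study conditions used throughout the
tests and the reproduction script:

* ``spectrum_scene``   -- 1 Mb genome, sparse genes; size-spectrum analyses.
* ``tss_scene``        -- 200 genes at 10 kb pitch; TSS footprint recovery.
* ``ess_scene``        -- 100 four-exon genes (300 interior exon starts).
* ``cohort_genome``    -- 4 x 1.2 Mb autosomes + 0.6 Mb chrX; clustering/CNV.
* ``make_patient``     -- patient-private germline deletions (50 homozygous,
  300-3000 bp, shared by every sample of that patient) plus an aneuploid
  somatic profile: per autosome 2 of 3 random segments altered to copy
  number in {1, 3, 4, 6}.
* ``focal_amp_spec``   -- the packaged focal-amplification fixture: a single
  500 kb segment at 20 copies on a 5 Mb autosome (patient-P1-style event).
* ``flat_scene``       -- one large flat diploid chromosome for GC-bias and
  normalization properties (thousands of 10 kb windows).

Every child seed is spawned deterministically from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import FeatureAnnotation, make_annotation
from .fragments import CnvSpec, Fragments, SamplingConfig, simulate_sample
from .genome import ToyGenome, make_genome
from .nucleosomes import NucleosomeMap, place_nucleosomes


def spawn_seeds(seed: int, n: int) -> list[int]:
    """n reproducible child seeds, each below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclass
class Scene:
    genome: ToyGenome
    annotation: FeatureAnnotation
    nucleosomes: NucleosomeMap


def spectrum_scene(seed: int = 0) -> Scene:
    g = make_genome(1, 1_000_000, ("sine", 0.30, 0.65, 250_000), seed=seed)
    ann = make_annotation(g, n_genes=10, exons_per_gene=3, seed=seed + 1)
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)


def tss_scene(seed: int = 0, n_genes: int = 200) -> Scene:
    g = make_genome(1, n_genes * 10_000, ("sine", 0.35, 0.55, 400_000), seed=seed)
    ann = make_annotation(g, n_genes=n_genes, exons_per_gene=3, seed=seed + 1)
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)


def ess_scene(seed: int = 0, n_genes: int = 100, exons_per_gene: int = 4) -> Scene:
    g = make_genome(1, n_genes * 10_000, ("sine", 0.35, 0.55, 400_000), seed=seed)
    ann = make_annotation(g, n_genes=n_genes, exons_per_gene=exons_per_gene,
                          seed=seed + 1)
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)


def add_promoter_gc(genome: ToyGenome, annotation: FeatureAnnotation,
                    bump: float = 0.12, sd: int = 300, half_width: int = 600,
                    seed: int = 0) -> ToyGenome:
    """Resample bases around each TSS with a CpG-island-like GC elevation.

    Real promoters are GC-rich; planting a Gaussian GC bump (height
    ``bump``, width ``sd``) at each TSS gives the per-base metagene GC
    profile the structure against which coverage bias can be measured.
    """
    rng = np.random.default_rng(seed)
    seqs = {c: genome.seqs[c].copy() for c in genome.chrom_names}
    offs = np.arange(-half_width, half_width)
    envelope = bump * np.exp(-(offs**2) / (2.0 * sd**2))
    for a in annotation.tss:
        L = len(seqs[a.chrom])
        lo, hi = a.pos - half_width, a.pos + half_width
        if lo < 0 or hi > L:
            continue
        window = slice(lo, hi)
        old = seqs[a.chrom][window]
        base_gc = ((old == ord("G")) | (old == ord("C"))).mean()
        target = np.clip(base_gc + envelope, 0.0, 1.0)
        is_gc = rng.random(offs.size) < target
        second = rng.random(offs.size) < 0.5
        new = np.where(
            is_gc,
            np.where(second, ord("G"), ord("C")),
            np.where(second, ord("A"), ord("T")),
        ).astype(np.uint8)
        keep_n = old == ord("N")
        new[keep_n] = ord("N")
        seqs[a.chrom][window] = new
    return ToyGenome(chrom_names=list(genome.chrom_names), seqs=seqs)


def promoter_gc_scene(seed: int = 0, n_genes: int = 200) -> Scene:
    """TSS scene whose promoters carry a CpG-island-like GC elevation."""
    base = tss_scene(seed, n_genes)
    genome = add_promoter_gc(base.genome, base.annotation, seed=seed + 3)
    ann = FeatureAnnotation(genome, base.annotation.genes)
    nmap = place_nucleosomes(genome, ann, seed=seed + 2)
    return Scene(genome, ann, nmap)


def flat_scene(seed: int = 0, length: int = 30_000_000) -> Scene:
    """One flat diploid chromosome with a smooth GC landscape; no genes."""
    g = make_genome(1, length, ("sine", 0.30, 0.65, 500_000), seed=seed)
    ann = FeatureAnnotation(g, [])
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

AUTOSOME_LEN = 1_200_000
SEX_LEN = 600_000
SOMATIC_CN_STATES = (1, 3, 4, 6)
N_PRIVATE_DELETIONS = 50
DELETION_SIZE_RANGE = (300, 3000)


def cohort_genome(seed: int = 0) -> Scene:
    g = make_genome(
        5,
        [AUTOSOME_LEN] * 4 + [SEX_LEN],
        ("sine", 0.30, 0.65, 300_000),
        n_gap_spec={"chr1": [(500_000, 520_000)]},
        seed=seed,
        chrom_names=["chr1", "chr2", "chr3", "chr4", "chrX"],
    )
    ann = make_annotation(g, n_genes=40, exons_per_gene=3, seed=seed + 1)
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)


@dataclass
class PatientSpec:
    patient_id: str
    private_deletions: tuple  # (chrom, start, end), homozygous, germline
    somatic_segments: tuple  # (chrom, start, end, cn)

    def cnv(self, tumor_fraction: float) -> CnvSpec:
        return CnvSpec(segments=self.somatic_segments,
                       tumor_fraction=tumor_fraction)


def make_patient(genome: ToyGenome, patient_id: str, seed: int) -> PatientSpec:
    rng = np.random.default_rng(seed)
    gaps = genome.n_gap_intervals

    # germline: private homozygous deletions anywhere outside N gaps
    dels: list[tuple[str, int, int]] = []
    while len(dels) < N_PRIVATE_DELETIONS:
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        size = int(rng.integers(DELETION_SIZE_RANGE[0], DELETION_SIZE_RANGE[1] + 1))
        s = int(rng.integers(0, genome.length(chrom) - size))
        e = s + size
        if any(s < ge and e > gs for gs, ge in gaps[chrom]):
            continue
        if any(c == chrom and s < de and e > ds for c, ds, de in dels):
            continue
        dels.append((chrom, s, e))

    # somatic: per autosome, 3 random segments, 2 altered
    segs: list[tuple[str, int, int, int]] = []
    for chrom in genome.chrom_names:
        if chrom.startswith("chrX") or chrom.startswith("chrY"):
            continue
        L = genome.length(chrom)
        w = 10_000
        cuts = np.sort(rng.choice(np.arange(10, L // w - 10), size=2, replace=False)) * w
        pieces = [(0, int(cuts[0])), (int(cuts[0]), int(cuts[1])), (int(cuts[1]), L)]
        altered = rng.choice(3, size=2, replace=False)
        for i, (s, e) in enumerate(pieces):
            if i in altered:
                cn = int(rng.choice(SOMATIC_CN_STATES))
                segs.append((chrom, s, e, cn))
    return PatientSpec(patient_id, tuple(dels), tuple(segs))


@dataclass
class CohortSample:
    sample_id: str
    patient_id: str
    sample_type: str
    fragments: Fragments


def simulate_patient_samples(
    scene: Scene,
    patient: PatientSpec,
    n_fragments: int = 100_000,
    cfdna_tumor_fraction: float = 0.5,
    seed: int = 0,
    sample_types: tuple = ("blood_gdna", "tumor_gdna", "plasma_cfdna"),
) -> list[CohortSample]:
    """Matched samples for one patient: diploid blood gDNA, pure sheared
    tumor gDNA (tf=1), and plasma cfDNA at the given tumor fraction."""
    seeds = spawn_seeds(seed, len(sample_types))
    out = []
    for stype, s in zip(sample_types, seeds):
        config = SamplingConfig.preset(
            stype, n_fragments, seed=s,
            patient_id=patient.patient_id,
            private_deletions=patient.private_deletions,
        )
        if stype == "blood_gdna":
            cnv = None
        elif stype == "tumor_gdna":
            cnv = patient.cnv(1.0)
        else:
            cnv = patient.cnv(cfdna_tumor_fraction)
        sid = f"{patient.patient_id}_{stype.split('_')[0]}"
        frags = simulate_sample(scene.genome, scene.nucleosomes, cnv, config, sid)
        out.append(CohortSample(sid, patient.patient_id, stype, frags))
    return out


def simulate_cohort(
    n_patients: int = 3,
    n_fragments: int = 100_000,
    cfdna_tumor_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[Scene, list[PatientSpec], list[CohortSample]]:
    scene = cohort_genome(seed)
    pseeds = spawn_seeds(seed + 1, 2 * n_patients)
    patients, samples = [], []
    for i in range(n_patients):
        patient = make_patient(scene.genome, f"P{i + 1}", pseeds[2 * i])
        patients.append(patient)
        samples.extend(simulate_patient_samples(
            scene, patient, n_fragments, cfdna_tumor_fraction,
            seed=pseeds[2 * i + 1],
        ))
    return scene, patients, samples


# ---------------------------------------------------------------------------
# focal amplification fixture
# ---------------------------------------------------------------------------

FOCAL_AMP_CHROM = "chr1"
FOCAL_AMP_START = 2_000_000
FOCAL_AMP_END = 2_500_000
FOCAL_AMP_COPY_NUMBER = 20


def focal_amp_spec(tumor_fraction: float = 1.0) -> CnvSpec:
    """A 500 kb, 20-copy focal amplification (patient-P1-style event)."""
    return CnvSpec(
        segments=((FOCAL_AMP_CHROM, FOCAL_AMP_START, FOCAL_AMP_END,
                   FOCAL_AMP_COPY_NUMBER),),
        tumor_fraction=tumor_fraction,
    )


def focal_amp_scene(seed: int = 0) -> Scene:
    g = make_genome(1, 5_000_000, ("sine", 0.30, 0.65, 400_000), seed=seed)
    ann = make_annotation(g, n_genes=20, exons_per_gene=3, seed=seed + 1)
    nmap = place_nucleosomes(g, ann, seed=seed + 2)
    return Scene(g, ann, nmap)
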