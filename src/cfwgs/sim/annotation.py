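"""Gene annotations: TSS/ESS/EES anchors and feature-class intervals.

Conventions (used package-wide):

* intervals are 0-based half-open ``[start, end)``;
* anchors are *edge* coordinates, gene-oriented: a plus-strand exon
  ``[s, e)`` has its exon start site (ESS) at ``s`` and exon end site (EES)
  at ``e``; a minus-strand exon has ESS at ``e`` and EES at ``s``;
* the relative coordinate of genomic position ``p`` with respect to anchor
  ``a`` is ``p - a`` on plus-strand genes and ``a - p`` on minus-strand genes;
* promoters are the anchor +/- 2000 bp, clipped to chromosome bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ToyGenome

PROMOTER_FLANK = 2000  # bp either side of the TSS
UTR5_LEN = 200  # leading gene-oriented bp of the first exon
UTR3_LEN = 300  # trailing gene-oriented bp of the last exon


@dataclass(frozen=True)
class Anchor:
    chrom: str
    pos: int
    strand: str  # "+" or "-"


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, disjoint, ascending

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> Anchor:
        pos = self.start if self.strand == "+" else self.end
        return Anchor(self.chrom, pos, self.strand)

    @property
    def ess(self) -> list[Anchor]:
        """Exon start sites in gene (transcription) order."""
        if self.strand == "+":
            return [Anchor(self.chrom, s, "+") for s, _ in self.exons]
        return [Anchor(self.chrom, e, "-") for _, e in reversed(self.exons)]

    @property
    def ees(self) -> list[Anchor]:
        """Exon end sites in gene (transcription) order."""
        if self.strand == "+":
            return [Anchor(self.chrom, e, "+") for _, e in self.exons]
        return [Anchor(self.chrom, s, "-") for s, _ in reversed(self.exons)]


class FeatureAnnotation:
    """Derived feature-class interval sets over a :class:`ToyGenome`."""

    def __init__(self, genome: ToyGenome, genes: list[Gene]):
        self.genome = genome
        self.genes = genes
        for g in genes:
            prev_end = -1
            for s, e in g.exons:
                if not (0 <= s < e <= genome.length(g.chrom)):
                    raise ValueError(f"exon [{s},{e}) outside {g.chrom} for {g.gene_id}")
                if s < prev_end:
                    raise ValueError(f"exons overlap/unordered in {g.gene_id}")
                prev_end = e

    # -- anchors ---------------------------------------------------------
    @property
    def tss(self) -> list[Anchor]:
        return [g.tss for g in self.genes]

    @property
    def ess(self) -> list[Anchor]:
        return [a for g in self.genes for a in g.ess]

    @property
    def ees(self) -> list[Anchor]:
        return [a for g in self.genes for a in g.ees]

    def interior_ess(self) -> list[Anchor]:
        """ESS anchors excluding each gene's first (TSS-coincident) exon."""
        return [a for g in self.genes for a in g.ess[1:]]

    # -- feature-class intervals ------------------------------------------
    @property
    def exon_intervals(self) -> list[tuple[str, int, int]]:
        return [(g.chrom, s, e) for g in self.genes for s, e in g.exons]

    @property
    def intron_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for g in self.genes:
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                out.append((g.chrom, e1, s2))
        return out

    @property
    def promoter_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for g in self.genes:
            a = g.tss
            lo = max(0, a.pos - PROMOTER_FLANK)
            hi = min(self.genome.length(a.chrom), a.pos + PROMOTER_FLANK)
            out.append((a.chrom, lo, hi))
        return out

    @property
    def utr5_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for g in self.genes:
            if g.strand == "+":
                s, e = g.exons[0]
                out.append((g.chrom, s, min(e, s + UTR5_LEN)))
            else:
                s, e = g.exons[-1]
                out.append((g.chrom, max(s, e - UTR5_LEN), e))
        return out

    @property
    def utr3_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for g in self.genes:
            if g.strand == "+":
                s, e = g.exons[-1]
                out.append((g.chrom, max(s, e - UTR3_LEN), e))
            else:
                s, e = g.exons[0]
                out.append((g.chrom, s, min(e, s + UTR3_LEN)))
        return out

    def feature_classes(self) -> dict[str, list[tuple[str, int, int]]]:
        return {
            "promoter": self.promoter_intervals,
            "utr5": self.utr5_intervals,
            "exon": self.exon_intervals,
            "intron": self.intron_intervals,
            "utr3": self.utr3_intervals,
        }

    # -- IO ---------------------------------------------------------------
    def write_bed(self, directory) -> None:
        """BED6 layers: tss.bed (with strand), exons.bed, promoters.bed, utr5.bed,
        utr3.bed, introns.bed."""
        import os

        os.makedirs(directory, exist_ok=True)

        def _write(path, rows):
            with open(path, "w") as fh:
                for chrom, s, e, name, strand in rows:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")

        _write(
            os.path.join(directory, "tss.bed"),
            [(a.chrom, a.pos, a.pos + 1, g.gene_id, a.strand)
             for g, a in ((g, g.tss) for g in self.genes)],
        )
        for fname, key in [("promoters.bed", "promoter"), ("utr5.bed", "utr5"),
                           ("exons.bed", "exon"), ("introns.bed", "intron"),
                           ("utr3.bed", "utr3")]:
            ivs = self.feature_classes()[key]
            _write(os.path.join(directory, fname),
                   [(c, s, e, f"{key}_{i}", ".") for i, (c, s, e) in enumerate(ivs)])


def make_annotation(
    genome: ToyGenome,
    n_genes: int,
    exons_per_gene: int = 3,
    strand_mix: float = 0.5,
    seed: int = 0,
    exon_len: int = 400,
    intron_len: int = 1400,
    flank: int = 1000,
) -> FeatureAnnotation:
    """Place ``n_genes`` equal-structure genes evenly across the genome.

    Genes are spread over chromosomes proportionally to length, each with
    ``exons_per_gene`` exons of ``exon_len`` bp separated by ``intron_len`` bp
    introns, and at least ``flank`` bp clear of chromosome ends and of each
    other.  Strand is Bernoulli(``strand_mix`` minus-strand) per gene.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    slot = gene_span + 2 * flank

    total = genome.total_length
    counts = {}
    remaining = n_genes
    for i, c in enumerate(genome.chrom_names):
        if i == len(genome.chrom_names) - 1:
            counts[c] = remaining
        else:
            k = int(round(n_genes * genome.length(c) / total))
            k = min(k, remaining)
            counts[c] = k
            remaining -= k

    genes: list[Gene] = []
    gi = 0
    for chrom in genome.chrom_names:
        k = counts[chrom]
        if k == 0:
            continue
        L = genome.length(chrom)
        if k * slot > L:
            raise ValueError(
                f"genome too small: {k} genes of slot {slot} bp do not fit in "
                f"{chrom} ({L} bp)"
            )
        pitch = L // k
        for j in range(k):
            start = j * pitch + (pitch - gene_span) // 2
            strand = "-" if rng.random() < strand_mix else "+"
            exons = [
                (start + t * (exon_len + intron_len),
                 start + t * (exon_len + intron_len) + exon_len)
                for t in range(exons_per_gene)
            ]
            genes.append(Gene(f"g{gi:04d}", chrom, strand, exons))
            gi += 1
    return FeatureAnnotation(genome, genes)
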