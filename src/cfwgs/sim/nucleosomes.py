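"""Planted nucleosome architectures around genomic anchors.

A :class:`NucleosomeMap` is the ground truth the boundary-profile analyses
recover: each dyad carries an occupancy in [0, 1] and a pre-trim protected
span ("width").  Default architectures:

TSS
    A nucleosome-depleted region (NDR) spanning gene-oriented (-170, 0),
    4 phased nucleosomes upstream at -250, -430, -610, -790 and 5 downstream
    at +90, +270, ..., +810 (180 bp repeat).  The +/-1000 bp zone is reserved:
    no other dyads are placed inside it.
ESS / EES
    Two sub-nucleosomal particles (120 bp span, occupancy 0.5) at +/-120 bp of
    the exon boundary -- these produce the four sharp sub-mononucleosomal
    boundary peaks within +/-200 bp -- plus two minor full nucleosomes at
    +/-350 bp (occupancy 0.4).  Reserved zone +/-500 bp.
Background
    Everywhere else, dyads every ``background_spacing`` bp with uniform
    jitter, occupancy 1, full span.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .annotation import Anchor, FeatureAnnotation
from .genome import ToyGenome

#: modal protected fragment length (chromatosome) in bp
PROTECTION_LEN = 167
#: sub-nucleosomal trimming quantum in bp
TRIM_QUANTUM = 10.6
#: pre-trim emitted span: cuts initiate one trim quantum into the linker
NUCLEOSOME_SPAN = PROTECTION_LEN + round(TRIM_QUANTUM)  # 178
#: pre-trim span of the exon-boundary particles
EXON_PARTICLE_SPAN = 120


@dataclass(frozen=True)
class Architecture:
    """Dyad layout relative to an anchor, gene-oriented.

    ``dyads`` are (offset_bp, occupancy, span_bp) triples; ``ndr`` is an
    optional gene-oriented nucleosome-free interval; ``reserve`` is the zone
    around the anchor in which lower-priority dyads are suppressed.
    """

    dyads: tuple[tuple[int, float, int], ...]
    ndr: tuple[int, int] | None = None
    reserve: tuple[int, int] = (-1000, 1000)

    def __post_init__(self):
        pts = sorted((o, s) for o, _q, s in self.dyads)
        for (o1, s1), (o2, s2) in zip(pts, pts[1:]):
            if o2 - o1 < (s1 + s2) / 2:
                raise ValueError(
                    f"architecture dyads at {o1} and {o2} overlap "
                    f"(spans {s1}/{s2})"
                )
        for _o, q, _s in self.dyads:
            if not 0.0 <= q <= 1.0:
                raise ValueError("occupancy must be in [0, 1]")


TSS_ARCHITECTURE = Architecture(
    dyads=tuple(
        [(-250 - 180 * k, 1.0, NUCLEOSOME_SPAN) for k in range(4)]
        + [(90 + 180 * k, 1.0, NUCLEOSOME_SPAN) for k in range(5)]
    ),
    ndr=(-170, 0),
    reserve=(-1000, 1000),
)

ESS_ARCHITECTURE = Architecture(
    dyads=(
        (-350, 0.4, NUCLEOSOME_SPAN),
        (-120, 0.5, EXON_PARTICLE_SPAN),
        (120, 0.5, EXON_PARTICLE_SPAN),
        (350, 0.4, NUCLEOSOME_SPAN),
    ),
    reserve=(-500, 500),
)

EES_ARCHITECTURE = ESS_ARCHITECTURE


@dataclass
class NucleosomeMap:
    """Per-chromosome dyad arrays plus planted NDR intervals."""

    chrom_names: list[str]
    pos: dict[str, np.ndarray]  # dyad centres, ascending
    occupancy: dict[str, np.ndarray]
    width: dict[str, np.ndarray]  # pre-trim protected span per dyad
    ndr_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for c in self.chrom_names:
            q = self.occupancy[c]
            if q.size and (q.min() < 0 or q.max() > 1):
                raise ValueError("occupancy outside [0, 1]")
            p, w = self.pos[c], self.width[c]
            if p.size > 1:
                gap = np.diff(p)
                min_gap = np.minimum((w[:-1] + w[1:]) / 2, PROTECTION_LEN)
                bad = np.flatnonzero(gap < min_gap)
                if bad.size:
                    i = int(bad[0])
                    raise ValueError(
                        f"dyads at {c}:{p[i]} and {c}:{p[i + 1]} closer than "
                        f"their protection length"
                    )
        for chrom, lo, hi in self.ndr_intervals:
            inside = (self.pos[chrom] >= lo) & (self.pos[chrom] < hi)
            if inside.any():
                raise ValueError(f"dyad inside NDR {chrom}:[{lo},{hi})")

    @property
    def n_dyads(self) -> int:
        return sum(int(self.pos[c].size) for c in self.chrom_names)


def _genomic(anchor: Anchor, offset: int) -> int:
    return anchor.pos + offset if anchor.strand == "+" else anchor.pos - offset


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [(a, b) for a, b in out]


def place_nucleosomes(
    genome: ToyGenome,
    annotation: FeatureAnnotation | None,
    tss_architecture: Architecture | None = None,
    ess_architecture: Architecture | None = None,
    ees_architecture: Architecture | None = None,
    background_spacing: int = 200,
    background_jitter: int = 60,
    seed: int = 0,
) -> NucleosomeMap:
    """Build the planted dyad map for a genome + annotation.

    Anchor architectures are laid down in priority order TSS > ESS > EES;
    a candidate dyad is dropped if it falls in a higher-priority reserved
    zone or within protection distance of an already-placed dyad.  The
    remaining genome (outside all reserved zones and N gaps, padded by one
    nucleosome span) is tiled with background dyads at ``background_spacing``
    plus uniform jitter in ``[-background_jitter, +background_jitter]``.
    """
    tss_arch = tss_architecture or TSS_ARCHITECTURE
    ess_arch = ess_architecture or ESS_ARCHITECTURE
    ees_arch = ees_architecture or EES_ARCHITECTURE
    rng = np.random.default_rng(seed)
    span = NUCLEOSOME_SPAN

    # per-chrom sorted anchor-dyad lists: (pos, occupancy, width)
    placed: dict[str, list[tuple[int, float, int]]] = {c: [] for c in genome.chrom_names}
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    ndrs: list[tuple[str, int, int]] = []

    def in_reserved(chrom: str, p: int) -> bool:
        zones = reserved[chrom]
        i = bisect.bisect_right(zones, (p, np.inf)) - 1
        return i >= 0 and zones[i][0] <= p < zones[i][1]

    def collides(chrom: str, p: int, w: int) -> bool:
        rows = placed[chrom]
        i = bisect.bisect_left(rows, (p, -1.0, -1))
        for j in (i - 1, i):
            if 0 <= j < len(rows):
                p0, _q0, w0 = rows[j]
                if abs(p - p0) < (w + w0) / 2:
                    return True
        return False

    def lay(anchors: list[Anchor], arch: Architecture):
        zones: dict[str, list[tuple[int, int]]] = {}
        for a in anchors:
            for off, q, w in arch.dyads:
                p = _genomic(a, off)
                if not (w // 2 <= p <= genome.length(a.chrom) - w // 2):
                    continue
                if in_reserved(a.chrom, p) or collides(a.chrom, p, w):
                    continue
                bisect.insort(placed[a.chrom], (p, q, w))
            if arch.ndr is not None:
                g0, g1 = _genomic(a, arch.ndr[0]), _genomic(a, arch.ndr[1])
                ndrs.append((a.chrom, min(g0, g1), max(g0, g1)))
            lo, hi = (_genomic(a, arch.reserve[0]), _genomic(a, arch.reserve[1]))
            zones.setdefault(a.chrom, []).append((min(lo, hi), max(lo, hi)))
        for chrom, zs in zones.items():
            reserved[chrom] = _merge(reserved[chrom] + zs)

    if annotation is not None:
        lay(annotation.tss, tss_arch)
        lay(annotation.ess, ess_arch)
        lay(annotation.ees, ees_arch)

    pos, occ, wid = {}, {}, {}
    for chrom in genome.chrom_names:
        # background candidates: jittered lattice over the whole chromosome,
        # then vectorized removal of blocked ones
        L = genome.length(chrom)
        n_cand = max(L // background_spacing + 2, 1)
        steps = background_spacing + rng.integers(
            -background_jitter, background_jitter + 1, size=n_cand
        )
        steps = np.maximum(steps, span + 5)
        cand = span // 2 + int(rng.integers(0, background_spacing)) + np.cumsum(steps)
        cand = cand[cand <= L - span // 2]

        blocked = _merge(
            [(lo - span, hi + span) for lo, hi in reserved[chrom]]
            + [(s - span, e + span) for s, e in genome.n_gap_intervals[chrom]]
        )
        if blocked:
            b_lo = np.array([b[0] for b in blocked])
            b_hi = np.array([b[1] for b in blocked])
            idx = np.searchsorted(b_lo, cand, side="right") - 1
            inside = (idx >= 0) & (cand < b_hi[np.clip(idx, 0, None)])
            cand = cand[~inside]

        rows = placed[chrom] + [(int(p), 1.0, span) for p in cand]
        rows.sort()
        pos[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
        occ[chrom] = np.array([r[1] for r in rows], dtype=np.float64)
        wid[chrom] = np.array([r[2] for r in rows], dtype=np.int64)

    return NucleosomeMap(
        chrom_names=list(genome.chrom_names),
        pos=pos,
        occupancy=occ,
        width=wid,
        ndr_intervals=ndrs,
    )
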