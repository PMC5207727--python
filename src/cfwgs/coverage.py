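"""Per-base fragment depth, cumulative coverage curves and uncovered catalogs.

Depth counts whole fragment spans (template intervals), not individual read
mates.  All denominators exclude N bases; sex chromosomes can be excluded
from uncovered-interval catalogs, matching how the study reports them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sim.annotation import FeatureAnnotation
from .sim.fragments import Fragments
from .sim.genome import ToyGenome, is_sex_chrom


@dataclass
class DepthTrack:
    """Fragment-level depth per chromosome (+1 per overlapping fragment)."""

    depth: dict[str, np.ndarray]
    genome: ToyGenome

    @property
    def mean_depth(self) -> float:
        """Total covered-bp mass divided by non-N genome length."""
        mass = sum(int(self.depth[c].sum()) for c in self.genome.chrom_names)
        return mass / self.genome.non_n_length()

    def non_n_mask(self, chrom: str) -> np.ndarray:
        m = np.ones(self.genome.length(chrom), dtype=bool)
        for s, e in self.genome.n_gap_intervals[chrom]:
            m[s:e] = False
        return m


@dataclass
class UncoveredCatalog:
    intervals: list[tuple[str, int, int]]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for _c, s, e in self.intervals], dtype=np.int64)


def depth_vector(fragments: Fragments, genome: ToyGenome) -> DepthTrack:
    """depth[p] = number of fragments whose half-open interval contains p."""
    depth = {c: np.zeros(genome.length(c), dtype=np.int32) for c in genome.chrom_names}
    for ci, chrom in enumerate(genome.chrom_names):
        m = fragments.chrom_idx == ci
        if not m.any():
            continue
        s, e = fragments.start[m], fragments.end[m]
        L = genome.length(chrom)
        if (s < 0).any() or (e > L).any():
            i = int(np.flatnonzero((s < 0) | (e > L))[0])
            raise ValueError(
                f"fragment outside {chrom} bounds: [{s[i]},{e[i]}) vs length {L}"
            )
        diff = np.zeros(L + 1, dtype=np.int64)
        np.add.at(diff, s, 1)
        np.add.at(diff, e, -1)
        depth[chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    return DepthTrack(depth, genome)


def cumulative_coverage_curve(track: DepthTrack, normalize: bool = False):
    """(depth, fraction of non-N genome covered by >= depth) pairs.

    With ``normalize`` the x axis is depth divided by the sample mean depth.
    The curve is monotone nonincreasing and starts at fraction 1 for d=0.
    """
    genome = track.genome
    if genome.non_n_length() == 0:
        raise ValueError("genome has no non-N positions")
    counts = None
    for chrom in genome.chrom_names:
        d = track.depth[chrom][track.non_n_mask(chrom)]
        bc = np.bincount(d)
        if counts is None:
            counts = bc.astype(np.int64)
        else:
            if bc.size > counts.size:
                bc, counts = counts, bc.astype(np.int64)
            counts[: bc.size] += bc
    frac_ge = np.cumsum(counts[::-1])[::-1] / counts.sum()
    depths = np.arange(counts.size, dtype=float)
    if normalize:
        depths = depths / track.mean_depth
    return depths, frac_ge


def _class_masks(annotation, genome: ToyGenome) -> dict[str, dict[str, np.ndarray]]:
    classes = (annotation.feature_classes()
               if isinstance(annotation, FeatureAnnotation) else annotation)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for cls, intervals in classes.items():
        per_chrom = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chrom_names}
        for chrom, s, e in intervals:
            per_chrom[chrom][s:e] = True
        masks[cls] = per_chrom
    return masks


def uncovered_by_feature(track: DepthTrack, annotation) -> dict[str, float]:
    """Fraction of non-N positions at depth 0, genome-wide and per feature
    class.  Classes are scored independently: a base may belong to several.

    ``annotation`` is a :class:`FeatureAnnotation` or a plain mapping of
    class name -> list of (chrom, start, end) intervals."""
    genome = track.genome
    out: dict[str, float] = {}
    zero_nonn = {}
    nonn = {}
    for chrom in genome.chrom_names:
        nn = track.non_n_mask(chrom)
        nonn[chrom] = nn
        zero_nonn[chrom] = nn & (track.depth[chrom] == 0)

    tot = sum(int(nonn[c].sum()) for c in genome.chrom_names)
    zer = sum(int(zero_nonn[c].sum()) for c in genome.chrom_names)
    out["genome"] = zer / tot if tot else float("nan")

    for cls, per_chrom in _class_masks(annotation, genome).items():
        denom = num = 0
        for chrom in genome.chrom_names:
            m = per_chrom[chrom] & nonn[chrom]
            denom += int(m.sum())
            num += int((zero_nonn[chrom] & m).sum())
        out[cls] = num / denom if denom else float("nan")
    return out


def uncovered_intervals(track: DepthTrack, genome: ToyGenome,
                        include_sex_chroms: bool = False) -> UncoveredCatalog:
    """Maximal runs of depth-0 non-N positions; N gaps split runs and are
    never reported themselves."""
    out: list[tuple[str, int, int]] = []
    for chrom in genome.chrom_names:
        if not include_sex_chroms and is_sex_chrom(chrom):
            continue
        zero = track.non_n_mask(chrom) & (track.depth[chrom] == 0)
        d = np.diff(np.concatenate([[0], zero.view(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return UncoveredCatalog(out)
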