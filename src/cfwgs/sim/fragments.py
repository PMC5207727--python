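"""cfDNA and sheared-gDNA fragment simulation.

Generation model for cfDNA (apoptotic, nucleosome-protected DNA):

1. a dyad is chosen with probability proportional to
   occupancy x copy-number weight x GC-bias factor, where the copy-number
   weight of a position with tumor copy number ``c`` at tumor fraction ``tf``
   is ``tf*c/2 + (1-tf)`` and the GC factor of the protected interval is
   ``exp(-gc_bias_strength * (GC - 0.35)^2)`` (monotone decreasing above 35%
   GC, the smooth bias LOESS normalization has to recover);
2. with probability ``phased_fraction`` the fragment comes from the
   positioned dyad; otherwise from a diffuse background position drawn with
   the same copy-number/GC weighting (cells whose nucleosomes are not phased
   at the reference positions -- this is what limits the TSS-proximal
   coverage dip to ~20%);
3. the pre-trim protected span (one trim quantum wider than the 167 bp
   chromatosome, i.e. cuts initiate in the linker) is centred on the dyad;
   with probability ``dinucleosome_fraction`` and an adjacent dyad within
   ``DI_MAX_GAP``, a two-nucleosome span of 2 x 167 bp centred on the pair
   midpoint is emitted instead;
4. each end is independently trimmed by ``round(k * trim_quantum)`` bp with
   ``k ~ Geometric(trim_geometric_p)`` (support 0, 1, ...), floored so the
   fragment keeps at least ``min_frag_len`` bp;
5. fragments overlapping an N gap or one of the patient's private germline
   deletions are redrawn.

Sheared gDNA controls instead draw lengths from a truncated normal
(mechanical shearing) and positions uniformly under the same copy-number/GC
weighting.  Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .genome import ToyGenome
from .nucleosomes import NUCLEOSOME_SPAN, PROTECTION_LEN, TRIM_QUANTUM, NucleosomeMap

#: maximum dyad-to-dyad gap still packaged as a dinucleosomal fragment
DI_MAX_GAP = 260
#: GC fraction at which the GC-bias factor peaks
GC_REF = 0.35

SAMPLE_TYPES = ("plasma_cfdna", "effusion_cfdna", "blood_gdna", "tumor_gdna")


class FragmentRecord(NamedTuple):
    chrom: str
    start: int
    end: int
    sample_id: str


@dataclass
class Fragments:
    """A set of sequenced fragments as parallel coordinate arrays."""

    chrom_idx: np.ndarray  # int32 index into chrom_names
    start: np.ndarray
    end: np.ndarray
    chrom_names: list[str]
    sample_id: str = ""

    def __len__(self) -> int:
        return int(self.chrom_idx.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def __iter__(self) -> Iterator[FragmentRecord]:
        for c, s, e in zip(self.chrom_idx, self.start, self.end):
            yield FragmentRecord(self.chrom_names[c], int(s), int(e), self.sample_id)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom_idx == self.chrom_names.index(chrom)

    def subset(self, mask: np.ndarray) -> "Fragments":
        return Fragments(self.chrom_idx[mask], self.start[mask], self.end[mask],
                         self.chrom_names, self.sample_id)

    @classmethod
    def concat(cls, parts: list["Fragments"], sample_id: str | None = None) -> "Fragments":
        names = parts[0].chrom_names
        for p in parts:
            if p.chrom_names != names:
                raise ValueError("chromosome name sets differ")
        return cls(
            np.concatenate([p.chrom_idx for p in parts]),
            np.concatenate([p.start for p in parts]),
            np.concatenate([p.end for p in parts]),
            names,
            sample_id if sample_id is not None else parts[0].sample_id,
        )


@dataclass(frozen=True)
class CnvSpec:
    """Planted somatic copy-number states diluted by tumor fraction.

    ``segments`` are (chrom, start, end, copy_number) with non-negative
    integer copy numbers; uncovered genome is implicitly at ``base_ploidy``.
    """

    segments: tuple = ()
    tumor_fraction: float = 1.0
    base_ploidy: int = 2

    def __post_init__(self):
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, cn in self.segments:
            if e <= s:
                raise ValueError(f"empty CNV segment [{s},{e})")
            if cn < 0 or int(cn) != cn:
                raise ValueError("copy_number must be a non-negative integer")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping CNV segments on {chrom}")

    @classmethod
    def flat(cls, tumor_fraction: float = 0.0) -> "CnvSpec":
        return cls(segments=(), tumor_fraction=tumor_fraction)

    def copy_number_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        cn = np.full(pos.shape, float(self.base_ploidy))
        for c, s, e, v in self.segments:
            if c == chrom:
                cn[(pos >= s) & (pos < e)] = float(v)
        return cn

    def weight_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Mixture weight tf*CN/2 + (1-tf) relative to a diploid genome."""
        tf = self.tumor_fraction
        cn = self.copy_number_at(chrom, pos)
        return tf * cn / self.base_ploidy + (1.0 - tf)


@dataclass(frozen=True)
class SamplingConfig:
    """Everything a single sample draw depends on, seed included."""

    n_fragments: int
    sample_type: str = "plasma_cfdna"
    seed: int = 0
    gc_bias_strength: float = 2.0
    protection_len: int = PROTECTION_LEN
    trim_quantum: float = TRIM_QUANTUM
    trim_geometric_p: float = 0.45
    min_frag_len: int = 80
    dinucleosome_fraction: float = 0.02
    phased_fraction: float = 0.16
    shear_mean: float = 350.0
    shear_sd: float = 35.0
    patient_id: str = "P0"
    private_deletions: tuple = ()  # (chrom, start, end) hard-masked intervals

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
        if not 0.0 < self.trim_geometric_p <= 1.0:
            raise ValueError("trim_geometric_p must be in (0, 1]")
        for name in ("dinucleosome_fraction", "phased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_frag_len >= self.protection_len:
            raise ValueError("min_frag_len must be smaller than protection_len")
        if self.gc_bias_strength < 0:
            raise ValueError("gc_bias_strength must be >= 0")

    @classmethod
    def preset(cls, sample_type: str, n_fragments: int, seed: int = 0, **over) -> "SamplingConfig":
        """Study-condition presets: plasma cfDNA carries a 2% dinucleosomal
        component, body-fluid effusion cfDNA 20%; gDNA types shear to 350 bp."""
        base = dict(n_fragments=n_fragments, sample_type=sample_type, seed=seed)
        if sample_type == "plasma_cfdna":
            base["dinucleosome_fraction"] = 0.02
        elif sample_type == "effusion_cfdna":
            base["dinucleosome_fraction"] = 0.2
        base.update(over)
        return cls(**base)


def _gc_factor(gc: np.ndarray, strength: float) -> np.ndarray:
    f = np.exp(-strength * (gc - GC_REF) ** 2)
    return np.where(np.isnan(gc), 0.0, f)


def _blocked_per_chrom(genome: ToyGenome, config: SamplingConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom in genome.chrom_names:
        ivs = list(genome.n_gap_intervals[chrom])
        ivs += [(s, e) for c, s, e in config.private_deletions if c == chrom]
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = (np.array([m[0] for m in merged], dtype=np.int64),
                      np.array([m[1] for m in merged], dtype=np.int64))
    return out


def _overlaps_blocked(blocked, chrom_idx, chrom_names, start, end) -> np.ndarray:
    hit = np.zeros(start.shape, dtype=bool)
    for ci, chrom in enumerate(chrom_names):
        b_lo, b_hi = blocked[chrom]
        if b_lo.size == 0:
            continue
        m = chrom_idx == ci
        if not m.any():
            continue
        idx = np.searchsorted(b_lo, end[m], side="left") - 1
        ok = idx >= 0
        over = np.zeros(idx.shape, dtype=bool)
        over[ok] = b_hi[idx[ok]] > start[m][ok]
        hit[m] = over
    return hit


def _trim_ends(rng, n, width, config) -> tuple[np.ndarray, np.ndarray]:
    """Geometric end trimming in quanta, floored at min_frag_len."""
    q = config.trim_quantum
    k1 = rng.geometric(config.trim_geometric_p, size=n) - 1
    k2 = rng.geometric(config.trim_geometric_p, size=n) - 1
    t1 = np.rint(k1 * q).astype(np.int64)
    t2 = np.rint(k2 * q).astype(np.int64)
    max_trim = np.maximum(width - config.min_frag_len, 0)
    over = np.maximum(t1 + t2 - max_trim, 0)
    red2 = np.minimum(over, t2)
    t2 -= red2
    over -= red2
    t1 -= np.minimum(over, t1)
    return t1, t2


def _rejection_positions(rng, genome, cnv_spec, config, n) -> tuple[np.ndarray, np.ndarray]:
    """Draw n genome positions with density ~ CN weight x GC factor."""
    lengths = np.array([genome.length(c) for c in genome.chrom_names], dtype=np.float64)
    p_chrom = lengths / lengths.sum()
    wmax = max(cnv_spec.tumor_fraction * cn / cnv_spec.base_ploidy + 1 - cnv_spec.tumor_fraction
               for cn in [cnv_spec.base_ploidy] + [s[3] for s in cnv_spec.segments])
    half = NUCLEOSOME_SPAN // 2
    out_c, out_p = [], []
    got = 0
    while got < n:
        m = max(int((n - got) / 0.5), 64)
        ci = rng.choice(len(lengths), size=m, p=p_chrom)
        pos = (rng.random(m) * lengths[ci]).astype(np.int64)
        w = np.empty(m)
        for k, chrom in enumerate(genome.chrom_names):
            msk = ci == k
            if not msk.any():
                continue
            pp = pos[msk]
            lo = np.clip(pp - half, 0, genome.length(chrom))
            hi = np.clip(pp + half, 0, genome.length(chrom))
            gc = genome.gc_fraction_many(chrom, lo, hi)
            w[msk] = cnv_spec.weight_at(chrom, pp) * _gc_factor(gc, config.gc_bias_strength)
        keep = rng.random(m) * wmax < w
        out_c.append(ci[keep])
        out_p.append(pos[keep])
        got += int(keep.sum())
    ci = np.concatenate(out_c)[:n]
    pos = np.concatenate(out_p)[:n]
    return ci.astype(np.int32), pos


def simulate_cfdna_fragments(
    genome: ToyGenome,
    nucleosome_map: NucleosomeMap,
    cnv_spec: CnvSpec | None,
    config: SamplingConfig,
    sample_id: str | None = None,
) -> Fragments:
    """Draw ``config.n_fragments`` nucleosome-protected cfDNA fragments."""
    if config.n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    if nucleosome_map.n_dyads == 0:
        raise ValueError("empty nucleosome map")
    cnv = cnv_spec if cnv_spec is not None else CnvSpec.flat()
    rng = np.random.default_rng(config.seed)
    blocked = _blocked_per_chrom(genome, config)

    # global dyad table + per-dyad selection weights
    d_ci = np.concatenate([
        np.full(nucleosome_map.pos[c].size, i, dtype=np.int32)
        for i, c in enumerate(genome.chrom_names)
    ])
    d_pos = np.concatenate([nucleosome_map.pos[c] for c in genome.chrom_names])
    d_occ = np.concatenate([nucleosome_map.occupancy[c] for c in genome.chrom_names])
    d_wid = np.concatenate([nucleosome_map.width[c] for c in genome.chrom_names])
    # distance to next dyad on the same chromosome (for dinucleosome pairing)
    d_gap = np.full(d_pos.size, np.iinfo(np.int64).max)
    off = 0
    for c in genome.chrom_names:
        k = nucleosome_map.pos[c].size
        if k > 1:
            d_gap[off : off + k - 1] = np.diff(nucleosome_map.pos[c])
        off += k

    w = d_occ.astype(np.float64).copy()
    for i, chrom in enumerate(genome.chrom_names):
        m = d_ci == i
        if not m.any():
            continue
        pp = d_pos[m]
        half = d_wid[m] // 2
        L = genome.length(chrom)
        lo = np.clip(pp - half, 0, L)
        hi = np.clip(pp + half, 0, L)
        gc = genome.gc_fraction_many(chrom, lo, hi)
        w[m] *= cnv.weight_at(chrom, pp) * _gc_factor(gc, config.gc_bias_strength)
        hit = _overlaps_blocked(blocked, np.full(pp.size, i, dtype=np.int32),
                                genome.chrom_names, lo, hi)
        wm = w[m]
        wm[hit] = 0.0
        w[m] = wm
    if w.sum() <= 0:
        raise ValueError("all dyads have zero sampling weight")
    p_dyad = w / w.sum()

    protection = config.protection_len
    di_span = 2 * protection

    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    need = config.n_fragments
    while need > 0:
        m = need
        idx = rng.choice(p_dyad.size, size=m, p=p_dyad)
        phased = rng.random(m) < config.phased_fraction
        di = rng.random(m) < config.dinucleosome_fraction

        ci = d_ci[idx].copy()
        center = d_pos[idx].astype(np.int64)
        width = d_wid[idx].copy()

        n_un = int((~phased).sum())
        if n_un:
            u_ci, u_pos = _rejection_positions(rng, genome, cnv, config, n_un)
            ci[~phased] = u_ci
            center[~phased] = u_pos
            width[~phased] = NUCLEOSOME_SPAN

        # dinucleosomal spans: pair with the next dyad when close enough
        pairable = di & phased & (d_gap[idx] <= DI_MAX_GAP)
        if pairable.any():
            j = idx[pairable]
            center[pairable] = (d_pos[j] + d_pos[j + 1]) // 2
            width[pairable] = di_span
        un_di = di & ~phased
        width[un_di] = di_span

        t1, t2 = _trim_ends(rng, m, width, config)
        start = center - width // 2 + t1
        end = center + (width - width // 2) - t2

        lens = np.array([genome.length(c) for c in genome.chrom_names], dtype=np.int64)
        ok = (start >= 0) & (end <= lens[ci]) & (end > start)
        ok &= ~_overlaps_blocked(blocked, ci, genome.chrom_names, start, end)
        parts.append((ci[ok], start[ok], end[ok]))
        need -= int(ok.sum())

    ci = np.concatenate([p[0] for p in parts])[: config.n_fragments]
    start = np.concatenate([p[1] for p in parts])[: config.n_fragments]
    end = np.concatenate([p[2] for p in parts])[: config.n_fragments]
    return Fragments(ci, start, end, list(genome.chrom_names),
                     sample_id or f"{config.patient_id}_{config.sample_type}")


def simulate_sheared_fragments(
    genome: ToyGenome,
    cnv_spec: CnvSpec | None,
    config: SamplingConfig,
    sample_id: str | None = None,
) -> Fragments:
    """Mechanically sheared gDNA: normal insert sizes, positions uniform up to
    copy-number and GC weighting.  Blood controls pass ``cnv_spec=None``
    (diploid everywhere); patient-private deletions are hard-masked either way.
    """
    if config.n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    cnv = cnv_spec if cnv_spec is not None else CnvSpec.flat()
    rng = np.random.default_rng(config.seed)
    blocked = _blocked_per_chrom(genome, config)
    lo_len, hi_len = 50, int(2 * config.shear_mean)

    lens = np.array([genome.length(c) for c in genome.chrom_names], dtype=np.int64)
    parts = []
    need = config.n_fragments
    while need > 0:
        m = need
        ci, center = _rejection_positions(rng, genome, cnv, config, m)
        flen = np.rint(rng.normal(config.shear_mean, config.shear_sd, size=m)).astype(np.int64)
        bad = (flen < lo_len) | (flen > hi_len)
        while bad.any():  # truncate by redraw
            flen[bad] = np.rint(
                rng.normal(config.shear_mean, config.shear_sd, size=int(bad.sum()))
            ).astype(np.int64)
            bad = (flen < lo_len) | (flen > hi_len)
        start = center - flen // 2
        end = start + flen
        ok = (start >= 0) & (end <= lens[ci])
        ok &= ~_overlaps_blocked(blocked, ci, genome.chrom_names, start, end)
        parts.append((ci[ok], start[ok], end[ok]))
        need -= int(ok.sum())

    ci = np.concatenate([p[0] for p in parts])[: config.n_fragments]
    start = np.concatenate([p[1] for p in parts])[: config.n_fragments]
    end = np.concatenate([p[2] for p in parts])[: config.n_fragments]
    return Fragments(ci, start, end, list(genome.chrom_names),
                     sample_id or f"{config.patient_id}_{config.sample_type}")


def simulate_sample(genome, nucleosome_map, cnv_spec, config, sample_id=None) -> Fragments:
    """Dispatch on sample type: cfDNA types are nucleosome-protected,
    gDNA types are sheared."""
    if config.sample_type in ("plasma_cfdna", "effusion_cfdna"):
        return simulate_cfdna_fragments(genome, nucleosome_map, cnv_spec, config, sample_id)
    return simulate_sheared_fragments(genome, cnv_spec, config, sample_id)
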