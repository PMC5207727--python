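"""Toy reference genomes with controlled GC landscapes and N gaps.

The downstream analyses (GC-bias normalization, windowed CNV, footprint
metagenes) only need a genome with a known base composition, so sequences
are generated rather than loaded: each chromosome gets a smooth per-kilobase
target GC profile and bases are drawn independently against it.  N gaps are
planted explicitly and excluded from every denominator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_A, _C, _G, _T, _N = (np.uint8(ord(c)) for c in "ACGTN")

#: chromosome names treated as sex chromosomes throughout the package
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def is_sex_chrom(name: str) -> bool:
    return name in SEX_CHROMS


@dataclass
class ToyGenome:
    """A small in-memory reference: per-chromosome byte arrays of A/C/G/T/N.

    ``seqs`` maps chromosome name to a ``uint8`` array of ASCII codes.
    GC lookups over arbitrary intervals are O(1) via cached cumulative sums.
    """

    chrom_names: list[str]
    seqs: dict[str, np.ndarray]
    _gc_cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _n_cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.seqs[name]
            gc = ((seq == _G) | (seq == _C)).astype(np.int64)
            nn = (seq == _N).astype(np.int64)
            self._gc_cum[name] = np.concatenate([[0], np.cumsum(gc)])
            self._n_cum[name] = np.concatenate([[0], np.cumsum(nn)])

    # -- basic geometry -------------------------------------------------
    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(self.seqs[c]) for c in self.chrom_names}

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def non_n_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return self.length(chrom) - int(self._n_cum[chrom][-1])
        return sum(self.non_n_length(c) for c in self.chrom_names)

    # -- composition ----------------------------------------------------
    def n_count(self, chrom: str, start: int, end: int) -> int:
        cum = self._n_cum[chrom]
        return int(cum[end] - cum[start])

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        """GC fraction of [start, end), N bases excluded from the denominator."""
        gc = self._gc_cum[chrom]
        denom = (end - start) - self.n_count(chrom, start, end)
        if denom <= 0:
            return float("nan")
        return float(gc[end] - gc[start]) / denom

    def gc_fraction_many(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        gc = self._gc_cum[chrom]
        nn = self._n_cum[chrom]
        denom = (ends - starts) - (nn[ends] - nn[starts])
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (gc[ends] - gc[starts]) / denom, np.nan)

    @property
    def n_gap_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Maximal runs of N per chromosome, 0-based half-open."""
        out: dict[str, list[tuple[int, int]]] = {}
        for name in self.chrom_names:
            isn = self.seqs[name] == _N
            if not isn.any():
                out[name] = []
                continue
            d = np.diff(np.concatenate([[0], isn.view(np.int8), [0]]))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            out[name] = list(zip(starts.tolist(), ends.tolist()))
        return out

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        return self.seqs[chrom][slice(start, end)].tobytes().decode("ascii")

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "ToyGenome":
        names: list[str] = []
        chunks: dict[str, list[bytes]] = {}
        current = None
        with open(path, "rb") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(b">"):
                    current = line[1:].split()[0].decode("ascii")
                    names.append(current)
                    chunks[current] = []
                else:
                    chunks[current].append(line.upper())
        seqs = {
            n: np.frombuffer(b"".join(chunks[n]), dtype=np.uint8).copy()
            for n in names
        }
        return cls(chrom_names=names, seqs=seqs)

    def write_fasta(self, path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequence(name)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def _target_gc_profile(length: int, spec) -> np.ndarray:
    """Per-base target GC from a landscape spec.

    Accepted specs (tuples):
      ``("uniform", g)``            flat composition
      ``("gradient", lo, hi)``      linear ramp lo -> hi along the chromosome
      ``("sine", lo, hi, period)``  smooth oscillation between lo and hi
    A bare float means uniform.
    """
    if isinstance(spec, (int, float)):
        spec = ("uniform", float(spec))
    kind = spec[0]
    x = np.arange(length, dtype=np.float64)
    if kind == "uniform":
        return np.full(length, float(spec[1]))
    if kind == "gradient":
        lo, hi = float(spec[1]), float(spec[2])
        return lo + (hi - lo) * x / max(length - 1, 1)
    if kind == "sine":
        lo, hi = float(spec[1]), float(spec[2])
        period = float(spec[3]) if len(spec) > 3 and spec[3] else length / 4.0
        mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
        return mid + amp * np.sin(2.0 * np.pi * x / period)
    raise ValueError(f"unknown gc_landscape_spec: {spec!r}")


def make_genome(
    n_chroms: int,
    lengths,
    gc_landscape_spec=("sine", 0.30, 0.65, None),
    n_gap_spec=None,
    seed: int = 0,
    chrom_names: list[str] | None = None,
) -> ToyGenome:
    """Generate a deterministic toy genome.

    Parameters
    ----------
    n_chroms, lengths
        Number of chromosomes and their lengths in bp (scalar or list).
    gc_landscape_spec
        See :func:`_target_gc_profile`; one spec for all chromosomes or a list
        of per-chromosome specs.
    n_gap_spec
        Mapping chrom name -> list of (start, end) intervals to hard-mask as N.
    chrom_names
        Defaults to ``chr1..chrN``; name a chromosome ``chrX``/``chrY`` to have
        it treated as a sex chromosome downstream.
    """
    if np.isscalar(lengths):
        lengths = [int(lengths)] * n_chroms
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chroms:
        raise ValueError("lengths must match n_chroms")
    for L in lengths:
        if L <= 0:
            raise ValueError(f"chromosome length must be positive, got {L}")
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    specs = gc_landscape_spec
    if not isinstance(specs, list):
        specs = [specs] * n_chroms

    rng = np.random.default_rng(seed)
    seqs: dict[str, np.ndarray] = {}
    for name, L, spec in zip(chrom_names, lengths, specs):
        target = _target_gc_profile(L, spec)
        u = rng.random(L)
        is_gc = u < target
        # within GC / AT, split 50:50
        second = rng.random(L) < 0.5
        seq = np.where(is_gc, np.where(second, _G, _C), np.where(second, _A, _T))
        seqs[name] = seq.astype(np.uint8)

    if n_gap_spec:
        for name, gaps in n_gap_spec.items():
            for s, e in gaps:
                if not (0 <= s < e <= len(seqs[name])):
                    raise ValueError(f"gap [{s},{e}) outside {name}")
                seqs[name][s:e] = _N

    return ToyGenome(chrom_names=chrom_names, seqs=seqs)
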