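"""Fragment table I/O: BED, BEDPE and SAM-compatible round trips.

BED records are 0-based half-open outer fragment spans.  BEDPE and SAM
records present the fragment as a proper 75 bp read pair (the study's
sequencing layout); the outer span, and hence |TLEN|, always equals the
fragment length.
"""

from __future__ import annotations

import numpy as np
import pysam

from .sim.fragments import Fragments

READ_LEN = 75
FORMATS = ("bed", "bedpe", "sam")


def _norm_format(fmt: str) -> str:
    f = fmt.lower()
    if f not in FORMATS:
        raise ValueError(f"unknown fragment format {fmt!r}; expected one of {FORMATS}")
    return f


def write_fragments(frags: Fragments, path, format: str = "bed",
                    chrom_lengths: dict[str, int] | None = None) -> None:
    fmt = _norm_format(format)
    if fmt == "bed":
        with open(path, "w") as fh:
            for i, (c, s, e) in enumerate(zip(frags.chrom_idx, frags.start, frags.end)):
                fh.write(f"{frags.chrom_names[c]}\t{s}\t{e}\t"
                         f"{frags.sample_id or 'frag'}_{i}\n")
        return
    if fmt == "bedpe":
        with open(path, "w") as fh:
            for i, (c, s, e) in enumerate(zip(frags.chrom_idx, frags.start, frags.end)):
                chrom = frags.chrom_names[c]
                e1 = min(s + READ_LEN, e)
                s2 = max(e - READ_LEN, s)
                fh.write(f"{chrom}\t{s}\t{e1}\t{chrom}\t{s2}\t{e}\t"
                         f"{frags.sample_id or 'frag'}_{i}\t0\t+\t-\n")
        return
    # SAM: proper pair, template length = fragment length
    if chrom_lengths is None:
        # fall back to the largest coordinate seen per chromosome
        chrom_lengths = {c: 1 for c in frags.chrom_names}
        for c, e in zip(frags.chrom_idx, frags.end):
            name = frags.chrom_names[c]
            chrom_lengths[name] = max(chrom_lengths[name], int(e))
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in frags.chrom_names],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (c, s, e) in enumerate(zip(frags.chrom_idx, frags.start, frags.end)):
            s, e = int(s), int(e)
            flen = e - s
            rlen = min(READ_LEN, flen)
            name = f"{frags.sample_id or 'frag'}_{i}"
            r1 = pysam.AlignedSegment(header)
            r1.query_name = name
            r1.flag = 99  # paired, proper, mate reverse, first in pair
            r1.reference_id = int(c)
            r1.reference_start = s
            r1.mapping_quality = 60
            r1.cigarstring = f"{rlen}M"
            r1.next_reference_id = int(c)
            r1.next_reference_start = e - rlen
            r1.template_length = flen
            r2 = pysam.AlignedSegment(header)
            r2.query_name = name
            r2.flag = 147  # paired, proper, reverse, second in pair
            r2.reference_id = int(c)
            r2.reference_start = e - rlen
            r2.mapping_quality = 60
            r2.cigarstring = f"{rlen}M"
            r2.next_reference_id = int(c)
            r2.next_reference_start = s
            r2.template_length = -flen
            out.write(r1)
            out.write(r2)


def read_fragments(path, format: str = "bed", sample_id: str = "") -> Fragments:
    fmt = _norm_format(format)
    chroms: list[str] = []
    cidx: dict[str, int] = {}
    ci, ss, ee = [], [], []

    def _add(chrom, s, e):
        if chrom not in cidx:
            cidx[chrom] = len(chroms)
            chroms.append(chrom)
        ci.append(cidx[chrom])
        ss.append(s)
        ee.append(e)

    if fmt in ("bed", "bedpe"):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if fmt == "bed":
                    _add(f[0], int(f[1]), int(f[2]))
                else:
                    _add(f[0], int(f[1]), int(f[5]))
    else:
        with pysam.AlignmentFile(str(path), "r") as fh:
            for r in fh:
                if r.is_read1 and r.is_proper_pair:
                    _add(r.reference_name, r.reference_start,
                         r.reference_start + abs(r.template_length))
    return Fragments(
        np.asarray(ci, dtype=np.int32),
        np.asarray(ss, dtype=np.int64),
        np.asarray(ee, dtype=np.int64),
        chroms,
        sample_id,
    )
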