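"""P-site assignment, reading frames, metagene profiles and region counts.

Footprints arrive as transcriptome alignments (SAM/BAM, read start = 5' end
in transcript coordinates) or as a plain TSV.  A per-sample offset table maps
read length to the distance from the 5' end to the P-site.  Frames are defined
relative to the CDS start, so frame 0 in the 3'-UTR means in-frame with the
CDS — the frame a readthrough ribosome occupies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .transcriptome import REGIONS, RegionMap, TranscriptModel, region_of

#: read lengths retained for analysis: 20-23 nt and 27-32 nt
DEFAULT_ALLOWED_LENGTHS = frozenset(range(20, 24)) | frozenset(range(27, 33))

#: P-sites in the first 15 and last 33 nt of the annotated CDS are excluded
#: from the trimmed CDS counts (ribosome queuing at start/stop codons)
DEFAULT_CDS_EXCLUDE = (15, 33)


@dataclass(frozen=True)
class RawRead:
    """A footprint before P-site assignment."""

    transcript_id: str
    five_prime: int  # 0-based transcript position of the 5' end
    length: int
    count: int = 1


@dataclass(frozen=True)
class FootprintRecord:
    transcript_id: str
    five_prime: int
    length: int
    psite: int
    frame: int = -1  # unset until a model is available
    count: int = 1


class OffsetTable:
    """Read length -> P-site offset from the 5' end, for one sample."""

    def __init__(self, offsets: Mapping[int, int], sample: str = "sample"):
        for length, off in offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} invalid for read length {length}")
        self.offsets = dict(offsets)
        self.sample = sample

    def __getitem__(self, length: int) -> int:
        try:
            return self.offsets[length]
        except KeyError:
            raise KeyError(f"no P-site offset for read length {length}") from None

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    @classmethod
    def from_tsv(cls, path: str, sample: str = "sample") -> "OffsetTable":
        offsets = {}
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields or fields[0] in ("length", "read_length"):
                    continue
                offsets[int(fields[0])] = int(fields[1])
        return cls(offsets, sample)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("length\toffset\n")
            for length in sorted(self.offsets):
                fh.write(f"{length}\t{self.offsets[length]}\n")


def filter_by_length(
    reads: Iterable[RawRead],
    allowed: frozenset[int] = DEFAULT_ALLOWED_LENGTHS,
) -> tuple[list[RawRead], Counter]:
    """Keep reads whose length falls in the allowed union; tally the rest."""
    kept, dropped = [], Counter()
    for r in reads:
        if r.length in allowed:
            kept.append(r)
        else:
            dropped[r.length] += r.count
    return kept, dropped


def assign_psite(read: RawRead, offsets: OffsetTable) -> FootprintRecord:
    """Shift the 5' end by the length-specific offset to locate the P-site."""
    return FootprintRecord(
        transcript_id=read.transcript_id,
        five_prime=read.five_prime,
        length=read.length,
        psite=read.five_prime + offsets[read.length],
        count=read.count,
    )


def frame_of(model: TranscriptModel, psite: int) -> int:
    """Reading frame of a P-site relative to the CDS start (floored modulo)."""
    if not 0 <= psite < model.length:
        raise ValueError(f"P-site {psite} out of range for {model.id}")
    return (psite - model.utr5_len) % 3


def annotate(
    records: Iterable[FootprintRecord],
    models: Mapping[str, TranscriptModel],
) -> tuple[list[FootprintRecord], Counter]:
    """Attach frames; drop records off-transcript or on unknown transcripts.

    Drops are tallied in a QC counter (P-sites can fall outside a transcript
    when UTR lengths were imputed).
    """
    out, qc = [], Counter()
    for rec in records:
        model = models.get(rec.transcript_id)
        if model is None:
            qc["unknown_transcript"] += rec.count
            continue
        if not 0 <= rec.psite < model.length:
            qc["psite_out_of_range"] += rec.count
            continue
        out.append(
            FootprintRecord(rec.transcript_id, rec.five_prime, rec.length,
                            rec.psite, frame_of(model, rec.psite), rec.count)
        )
    return out, qc


@dataclass
class RegionFrameCounts:
    """Per-gene footprint counts by region and frame."""

    gene: str
    counts: dict  # region -> np.ndarray of 3 frame counts
    counts_cds_trimmed: np.ndarray  # frame counts, CDS edge zones excluded
    library_total: int = 0
    trimmed_undefined: bool = False

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))


def count_region_frames(
    records: Iterable[FootprintRecord],
    models: Mapping[str, TranscriptModel],
    regionmaps: Mapping[str, RegionMap],
    cds_exclude: tuple[int, int] = DEFAULT_CDS_EXCLUDE,
    stop_in_cds: bool = False,
) -> dict[str, RegionFrameCounts]:
    """Tally frame-annotated P-sites into the four analysis regions.

    ``counts_cds_trimmed`` additionally excludes P-sites in the first
    ``cds_exclude[0]`` and last ``cds_exclude[1]`` nt of the annotated CDS
    (stop codon included); genes whose CDS is shorter than the two zones plus
    one codon get ``trimmed_undefined=True``.
    """
    lo_excl, hi_excl = cds_exclude
    out = {
        gid: RegionFrameCounts(
            gene=gid,
            counts={r: np.zeros(3, dtype=np.int64) for r in REGIONS},
            counts_cds_trimmed=np.zeros(3, dtype=np.int64),
            trimmed_undefined=models[gid].cds_len < lo_excl + hi_excl + 3,
        )
        for gid in models
    }
    library_total = 0
    for rec in records:
        model = models.get(rec.transcript_id)
        if model is None:
            continue
        rfc = out[rec.transcript_id]
        label = region_of(model, regionmaps[rec.transcript_id], rec.psite,
                          stop_in_cds=stop_in_cds)
        rfc.counts[label][rec.frame] += rec.count
        library_total += rec.count
        if (
            not rfc.trimmed_undefined
            and model.cds_start + lo_excl <= rec.psite < model.cds_end - hi_excl
        ):
            rfc.counts_cds_trimmed[rec.frame] += rec.count
    for rfc in out.values():
        rfc.library_total = library_total
    return out


def frame_fractions(counts: RegionFrameCounts, region: str) -> tuple[float, float, float] | None:
    """Per-frame read fractions for one region; None when the region is empty."""
    arr = counts.counts[region]
    total = int(arr.sum())
    if total == 0:
        return None
    return tuple(float(c) / total for c in arr)


def pooled_frame_fractions(
    all_counts: Mapping[str, RegionFrameCounts], region: str
) -> tuple[float, float, float] | None:
    pooled = np.zeros(3, dtype=np.int64)
    for rfc in all_counts.values():
        pooled += rfc.counts[region]
    total = int(pooled.sum())
    if total == 0:
        return None
    return tuple(float(c) / total for c in pooled)


@dataclass
class MetageneProfile:
    anchor: str  # "start" or "stop"
    window: tuple[int, int]
    positions: np.ndarray
    fractions: np.ndarray


def metagene_profile(
    records: Iterable[FootprintRecord],
    models: Mapping[str, TranscriptModel],
    anchor: str = "stop",
    window: tuple[int, int] = (-40, 80),
) -> MetageneProfile:
    """Pooled P-site density around the start or stop codon.

    Positions are P-site offsets relative to the first nucleotide of the
    anchor codon; counts are pooled across genes and divided by the window
    grand total (no per-gene normalisation before pooling).
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    lo, hi = window
    positions = np.arange(lo, hi + 1)
    totals = np.zeros(positions.size, dtype=np.float64)
    for rec in records:
        model = models.get(rec.transcript_id)
        if model is None:
            continue
        ref = model.cds_start if anchor == "start" else model.stop_start
        rel = rec.psite - ref
        if lo <= rel <= hi:
            totals[rel - lo] += rec.count
    grand = totals.sum()
    if grand > 0:
        totals /= grand
    return MetageneProfile(anchor, window, positions, totals)


# ---------------------------------------------------------------------------
# I/O


def load_reads_tsv(path: str) -> list[RawRead]:
    """TSV columns: transcript_id, five_prime (0-based), length[, count]."""
    reads = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields[0] in ("", "transcript_id"):
                continue
            count = int(fields[3]) if len(fields) > 3 else 1
            reads.append(RawRead(fields[0], int(fields[1]), int(fields[2]), count))
    return reads


def write_reads_tsv(reads: Iterable[RawRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tfive_prime\tlength\tcount\n")
        for r in reads:
            fh.write(f"{r.transcript_id}\t{r.five_prime}\t{r.length}\t{r.count}\n")


def load_reads_sam(path: str) -> list[RawRead]:
    """Read a transcriptome SAM/BAM; the alignment start is the 5' end.

    Reverse-strand and unmapped alignments are skipped (footprints align to
    the transcriptome in the sense orientation).
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_reverse:
                continue
            reads.append(RawRead(aln.reference_name, aln.reference_start,
                                 aln.query_length or aln.infer_read_length()))
    return reads


def write_region_frame_tsv(all_counts: Mapping[str, RegionFrameCounts], path: str) -> None:
    with open(path, "w") as fh:
        cols = [f"{r}_f{f}" for r in REGIONS for f in range(3)]
        fh.write("gene\t" + "\t".join(cols)
                 + "\tcds_trim_f0\tcds_trim_f1\tcds_trim_f2\tlibrary_total\n")
        for gid in sorted(all_counts):
            rfc = all_counts[gid]
            vals = [str(int(rfc.counts[r][f])) for r in REGIONS for f in range(3)]
            vals += [str(int(v)) for v in rfc.counts_cds_trimmed]
            vals.append(str(rfc.library_total))
            fh.write(gid + "\t" + "\t".join(vals) + "\n")
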