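"""Adjusted readthrough-efficiency statistic, expression filters and grouping.

Readthrough efficiency (RE) is the log2 ratio of frame-0 footprint density in
the adjusted 3'-UTR (canonical stop codon + annotated 3'-UTR) to frame-0
density in the edge-trimmed CDS:

    log2 RE = log2[ (n_f0_utr3 / utr3_len_adj) / (n_f0_cds_trim / cds_trim_len) ]

Only frame-0 P-sites enter either count — readthrough is by definition
in-frame with the CDS — and CDS P-sites within the first 15 / last 33 nt are
excluded to discount ribosome queuing at start and stop codons.  No exclusion
is applied around the downstream stop (many extensions are shorter than the
exclusion zone), so a frame-0 pile-up there inflates the numerator slightly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .footprints import FootprintRecord, RegionFrameCounts
from .transcriptome import RegionMap, TranscriptModel

MIN_RPKM_CDS = 5.0
MIN_RPKM_UTR3 = 0.5
HIGH_LOW_FRACTION = 0.15


def rpkm(count: float, region_len: int, library_total: int) -> float:
    """Reads per kilobase of region per million library reads."""
    if region_len <= 0:
        raise ValueError("region length must be positive")
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / (region_len / 1e3) / (library_total / 1e6)


@dataclass
class ReadthroughEstimate:
    gene: str
    n_f0_cds_trimmed: int
    n_f0_utr3: int
    cds_trimmed_len: int
    utr3_len_adj: int
    log2_re: float  # nan when undefined, -inf when numerator count is 0
    rpkm_cds: float
    rpkm_utr3: float
    passes_filter: bool = False
    group: str = "NA"  # High / Low / Mid / NA

    @property
    def finite(self) -> bool:
        return math.isfinite(self.log2_re)


def compute_readthrough_efficiency(
    counts: RegionFrameCounts,
    model: TranscriptModel,
    regionmap: RegionMap,
    cds_exclude: tuple[int, int] = (15, 33),
    numerator: str = "utr3",
    include_stop_in_denominator_len: bool = True,
) -> ReadthroughEstimate:
    """Per-gene adjusted RE from region-frame counts.

    ``numerator="utr3"`` (default) uses all frame-0 P-sites in the adjusted
    3'-UTR; ``numerator="extension"`` restricts to the extension region.
    A gene with no trimmed frame-0 CDS reads yields NaN (undefined); one with
    CDS signal but zero 3'-UTR frame-0 reads yields ``-inf`` (excluded from
    ranked analyses, retained for filtering bookkeeping).
    """
    f0_ext = int(counts.counts["extension"][0])
    f0_dist = int(counts.counts["distal_utr3"][0])
    if numerator == "utr3":
        n_num = f0_ext + f0_dist
    elif numerator == "extension":
        n_num = f0_ext
    else:
        raise ValueError(f"unknown numerator {numerator!r}")
    n_cds = int(counts.counts_cds_trimmed[0])

    trim_len = model.cds_len - cds_exclude[0] - cds_exclude[1]
    if numerator == "extension":
        num_len = regionmap.ext[1] - regionmap.ext[0]
    else:
        num_len = model.utr3_len + (3 if include_stop_in_denominator_len else 0)

    if counts.trimmed_undefined or n_cds == 0 or trim_len <= 0 or num_len <= 0:
        log2_re = math.nan
    elif n_num == 0:
        log2_re = -math.inf
    else:
        log2_re = math.log2((n_num / num_len) / (n_cds / trim_len))

    cds_all = int(counts.counts["cds"].sum())
    utr3_all = int(counts.counts["extension"].sum() + counts.counts["distal_utr3"].sum())
    lib = max(counts.library_total, 1)
    return ReadthroughEstimate(
        gene=counts.gene,
        n_f0_cds_trimmed=n_cds,
        n_f0_utr3=n_num,
        cds_trimmed_len=max(trim_len, 0),
        utr3_len_adj=max(num_len, 0),
        log2_re=log2_re,
        rpkm_cds=rpkm(cds_all, model.cds_len - 3, lib) if model.cds_len > 3 else 0.0,
        rpkm_utr3=rpkm(utr3_all, model.utr3_len + 3, lib),
    )


def apply_expression_filters(
    estimates: Iterable[ReadthroughEstimate],
    min_rpkm_cds: float = MIN_RPKM_CDS,
    min_rpkm_utr3: float = MIN_RPKM_UTR3,
    conjunctive: bool = True,
) -> list[ReadthroughEstimate]:
    """Flag poorly-expressed genes.

    Default (conjunctive) reading: discard genes with *both* CDS RPKM below
    ``min_rpkm_cds`` and 3'-UTR RPKM below ``min_rpkm_utr3``.  The disjunctive
    alternative discards a gene failing either threshold.
    """
    out = []
    for est in estimates:
        below_cds = est.rpkm_cds < min_rpkm_cds
        below_utr3 = est.rpkm_utr3 < min_rpkm_utr3
        fails = (below_cds and below_utr3) if conjunctive else (below_cds or below_utr3)
        out.append(replace(est, passes_filter=not fails))
    return out


def classify_high_low(
    estimates: Sequence[ReadthroughEstimate],
    fraction: float = HIGH_LOW_FRACTION,
) -> list[ReadthroughEstimate]:
    """Label the top/bottom ``fraction`` of filtered, finite estimates.

    Group sizes are floor(fraction * n) with ties broken by stable gene-id
    order; genes failing the expression filter or without a finite estimate
    are labelled NA.
    """
    eligible = [e for e in estimates if e.passes_filter and e.finite]
    n = len(eligible)
    n_sel = int(math.floor(fraction * n + 1e-9))
    if n_sel < 1:
        raise ValueError(f"too few genes ({n}) for fraction {fraction}")
    values = [e.log2_re for e in eligible]
    if max(values) == min(values):
        raise ValueError("all readthrough estimates identical; quantiles undefined")
    ranked = sorted(eligible, key=lambda e: (e.log2_re, e.gene))
    low = {e.gene for e in ranked[:n_sel]}
    high = {e.gene for e in ranked[-n_sel:]}
    out = []
    for est in estimates:
        if est.gene in high:
            grp = "High"
        elif est.gene in low:
            grp = "Low"
        elif est.passes_filter and est.finite:
            grp = "Mid"
        else:
            grp = "NA"
        out.append(replace(est, group=grp))
    return out


@dataclass
class PTCReadthrough:
    gene: str
    ptc_pos: int
    n_f0_down: int
    n_f0_up: int
    ratio: float  # nan when no upstream frame-0 reads


def ptc_readthrough(
    records: Iterable[FootprintRecord],
    model: TranscriptModel,
    ptc_pos: int,
) -> PTCReadthrough:
    """Frame-0 footprint count downstream vs upstream of a premature stop.

    ``ptc_pos`` is the transcript position of the first nucleotide of an
    in-frame stop codon within the CDS.  The ratio of in-frame counts
    downstream (through the CDS end) to upstream automatically normalises for
    mRNA level.
    """
    if not model.cds_start <= ptc_pos < model.stop_start:
        raise ValueError(f"PTC position {ptc_pos} not inside the CDS of {model.id}")
    if (ptc_pos - model.cds_start) % 3 != 0:
        raise ValueError(f"PTC position {ptc_pos} not in frame with the CDS")
    n_up = n_down = 0
    for rec in records:
        if rec.transcript_id != model.id or rec.frame != 0:
            continue
        if model.cds_start <= rec.psite < ptc_pos:
            n_up += rec.count
        elif ptc_pos + 3 <= rec.psite < model.cds_end:
            n_down += rec.count
    ratio = n_down / n_up if n_up > 0 else math.nan
    return PTCReadthrough(model.id, ptc_pos, n_down, n_up, ratio)


def write_estimates_tsv(estimates: Iterable[ReadthroughEstimate], path) -> None:
    buf = path if hasattr(path, "write") else open(path, "w")
    try:
        buf.write("gene\tn_f0_cds_trimmed\tn_f0_utr3\tcds_trimmed_len\tutr3_len_adj"
                  "\tlog2_re\trpkm_cds\trpkm_utr3\tpasses_filter\tgroup\n")
        for e in estimates:
            buf.write(
                f"{e.gene}\t{e.n_f0_cds_trimmed}\t{e.n_f0_utr3}\t{e.cds_trimmed_len}"
                f"\t{e.utr3_len_adj}\t{e.log2_re:.6g}\t{e.rpkm_cds:.6g}"
                f"\t{e.rpkm_utr3:.6g}\t{int(e.passes_filter)}\t{e.group}\n"
            )
    finally:
        if not hasattr(path, "write"):
            buf.close()


def read_estimates_tsv(path: str) -> list[ReadthroughEstimate]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        ReadthroughEstimate(
            gene=row.gene,
            n_f0_cds_trimmed=int(row.n_f0_cds_trimmed),
            n_f0_utr3=int(row.n_f0_utr3),
            cds_trimmed_len=int(row.cds_trimmed_len),
            utr3_len_adj=int(row.utr3_len_adj),
            log2_re=float(row.log2_re),
            rpkm_cds=float(row.rpkm_cds),
            rpkm_utr3=float(row.rpkm_utr3),
            passes_filter=bool(row.passes_filter),
            group=str(row.group),
        )
        for row in df.itertuples()
    ]
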