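"""Synthetic transcriptomes and footprint libraries with known ground truth.

The generator emulates the phenomena the pipeline measures: per-gene
programmed readthrough efficiency (a log2-scale additive model over
stop-codon context features plus gene noise), triplet periodicity with a
configurable frame-fidelity, ribosome stall pile-ups at the penultimate
codon and at the first downstream in-frame stop, and the bimodal footprint
length distribution (20-23 and 27-32 nt).  Frame-0 read counts are Poisson
per codon-grid position: density λ reads/nt in the CDS and λ·2^(log2 RE) in
the adjusted 3'-UTR, placed uniformly within each region.

Everything is reproducible under a single integer seed, and every writer
round-trips through the corresponding pipeline reader.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .footprints import FootprintRecord, OffsetTable, RawRead
from .transcriptome import (DEFAULT_UTR3, DEFAULT_UTR5, STOP_CODONS, RegionMap,
                            TranscriptModel, locate_extension)

NTS = ("A", "C", "G", "U")
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NTS, repeat=3)
    if "".join(c) not in STOP_CODONS
)

#: approximate S. cerevisiae stop-codon usage
DEFAULT_STOP_FREQS = {"UAA": 0.47, "UAG": 0.23, "UGA": 0.30}

DEFAULT_OFFSETS = {20: 8, 21: 9, 22: 9, 23: 10,
                   27: 11, 28: 12, 29: 12, 30: 13, 31: 13, 32: 14}

DEFAULT_LENGTH_WEIGHTS = {20: 2, 21: 3, 22: 3, 23: 2,
                          27: 5, 28: 20, 29: 25, 30: 20, 31: 12, 32: 8}


@dataclass
class SyntheticConfig:
    n_genes: int = 200
    seed: int = 0
    utr5_range: tuple[int, int] = (60, 150)
    cds_codon_range: tuple[int, int] = (100, 500)  # sense+stop codons
    utr3_codon_range: tuple[int, int] = (40, 80)  # post-stop 3'-UTR, codons
    ext_codon_range: tuple[int, int] = (1, 12)  # codons before the downstream stop
    cds_read_density: float = 0.5  # λ, frame-0 reads per CDS nt
    re_mean: float = -4.0  # baseline log2 readthrough efficiency
    re_sd: float = 1.0  # gene-to-gene noise, log2 units
    effect_map: dict = field(default_factory=dict)  # (feature, level) -> log2 shift
    stop_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_STOP_FREQS))
    nt_p4_freqs: Mapping[str, float] | None = None  # default uniform
    stop_nt4_coupling: dict = field(default_factory=dict)  # (stop, nt4) -> odds multiplier
    frame_fidelity: float = 0.9  # fraction of 3'-UTR reads in frame 0
    offframe_cds_noise: float = 0.05  # off-frame CDS reads relative to frame 0
    stall_multiplier: float = 1.0  # pile-up at penultimate codon / downstream stop
    frac_annotated: float = 1.0  # genes with experimental UTR annotation
    length_weights: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    offsets: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    rnaseq_depth: float = 1e6

    def offset_table(self) -> OffsetTable:
        return OffsetTable(dict(self.offsets), sample="synthetic")


def _choice(rng: np.random.Generator, items: Sequence[str], probs=None) -> str:
    return str(rng.choice(np.asarray(items, dtype=object), p=probs))


_NT_ARR = np.array(list(NTS))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT_ARR[rng.integers(0, 4, size=n)])


def _random_sense(rng: np.random.Generator, n: int, first_nt: str | None = None) -> list[str]:
    codons = []
    if first_nt is not None:
        pool = [c for c in SENSE_CODONS if c[0] == first_nt]
        codons.append(_choice(rng, pool))
        n -= 1
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    codons.extend(SENSE_CODONS[i] for i in idx)
    return codons


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[dict[str, TranscriptModel], pd.DataFrame]:
    """Random transcript models plus a per-gene ground-truth table.

    Sequences carry an AUG start, a stop-free CDS interior, a stop codon and
    nt+4 drawn from configured frequencies (with optional stop↔nt+4 odds
    coupling), and a guaranteed in-frame downstream stop at a sampled codon
    distance.  ``true_log2_re`` is filled in by :func:`assign_true_re`.
    """
    rng = np.random.default_rng(config.seed)
    lo_e, hi_e = config.ext_codon_range
    if hi_e + 1 > config.utr3_codon_range[0]:
        raise ValueError("extension range exceeds minimum 3'-UTR length")
    stops = list(config.stop_freqs)
    stop_p = np.array([config.stop_freqs[s] for s in stops], dtype=float)
    stop_p /= stop_p.sum()
    base_p4 = (dict.fromkeys(NTS, 0.25) if config.nt_p4_freqs is None
               else dict(config.nt_p4_freqs))

    models: dict[str, TranscriptModel] = {}
    rows = []
    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        annotated = bool(rng.random() < config.frac_annotated)
        if annotated:
            utr5_len = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
            utr3_len = 3 * int(rng.integers(config.utr3_codon_range[0],
                                            config.utr3_codon_range[1] + 1))
        else:
            utr5_len, utr3_len = DEFAULT_UTR5, DEFAULT_UTR3
        n_codons = int(rng.integers(config.cds_codon_range[0],
                                    config.cds_codon_range[1] + 1))

        stop = _choice(rng, stops, stop_p)
        w = np.array([base_p4[nt] * config.stop_nt4_coupling.get((stop, nt), 1.0)
                      for nt in NTS])
        nt_p4 = _choice(rng, NTS, w / w.sum())

        utr5 = _random_nt(rng, utr5_len)
        interior = _random_sense(rng, n_codons - 2)
        cds = "AUG" + "".join(interior) + stop

        max_d = min(hi_e, utr3_len // 3 - 1)
        d = int(rng.integers(max(lo_e, 1), max_d + 1))
        pre = _random_sense(rng, d, first_nt=nt_p4)
        down_stop = _choice(rng, sorted(STOP_CODONS))
        n_tail = utr3_len // 3 - d - 1
        tail = _random_nt(rng, 3 * n_tail + utr3_len % 3)
        utr3 = "".join(pre) + down_stop + tail

        model = TranscriptModel(
            id=gid, seq=utr5 + cds + utr3, utr5_len=utr5_len,
            cds_len=3 * n_codons, utr3_len=utr3_len, utr3_annotated=annotated,
        )
        assert not model.validate(), model.validate()
        models[gid] = model
        rows.append({
            "gene": gid, "stop_codon": stop, "nt_p4": nt_p4,
            "ext_codons": d, "utr5_len": utr5_len, "cds_len": 3 * n_codons,
            "utr3_len": utr3_len, "utr3_annotated": annotated,
            "true_log2_re": np.nan,
        })
    truth = pd.DataFrame(rows).set_index("gene")
    return models, truth


def assign_true_re(
    truth: pd.DataFrame,
    effect_map: Mapping[tuple[str, str], float],
    noise_sd: float,
    baseline: float = -4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Additive log2-scale model: baseline + feature effects + gene noise."""
    rng = np.random.default_rng(seed)
    re = np.full(len(truth), baseline, dtype=float)
    for (feature, level), shift in effect_map.items():
        re += np.where(truth[feature].astype(str) == level, shift, 0.0)
    re += rng.normal(0.0, noise_sd, size=len(truth))
    out = truth.copy()
    out["true_log2_re"] = re
    return out


def _emit(rng, records, gid, positions, counts, lengths, length_p, offsets):
    """Append one aggregated record per covered grid position."""
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        return
    lens = rng.choice(lengths, size=nz.size, p=length_p)
    for j, li in zip(nz, lens):
        psite = int(positions[j])
        length = int(li)
        records.append(FootprintRecord(
            transcript_id=gid, five_prime=psite - offsets[length],
            length=length, psite=psite, frame=-1, count=int(counts[j]),
        ))


def simulate_footprints(
    models: Mapping[str, TranscriptModel],
    truth: pd.DataFrame,
    config: SyntheticConfig,
    seed: int | None = None,
) -> list[RawRead]:
    """Poisson footprint library over the synthetic transcriptome.

    Frame-0 counts per codon-grid position are Poisson with per-nt density
    λ in the CDS and λ·2^true_log2_re in the adjusted 3'-UTR; off-frame reads
    are added per ``offframe_cds_noise`` (CDS) and ``frame_fidelity``
    (3'-UTR); ``stall_multiplier`` scales extra frame-0 pile-ups at the
    penultimate codon and the first downstream in-frame stop.  Returns raw
    reads (5' end + length); P-sites are recovered by the pipeline via the
    offset table.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    offsets = dict(config.offsets)
    lengths = np.array(sorted(config.length_weights), dtype=int)
    length_p = np.array([config.length_weights[l] for l in lengths], dtype=float)
    length_p /= length_p.sum()
    lam = config.cds_read_density
    records: list[FootprintRecord] = []

    for gid in sorted(models):
        model = models[gid]
        re = float(truth.loc[gid, "true_log2_re"])
        if not math.isfinite(re):
            raise ValueError(f"{gid}: true_log2_re not assigned")
        lam_utr = lam * 2.0 ** re

        # frame-0 CDS grid (stop codon position excluded; stall handles it)
        grid = np.arange(model.cds_start, model.stop_start, 3)
        counts = rng.poisson(3.0 * lam, size=grid.size)
        _emit(rng, records, gid, grid, counts, lengths, length_p, offsets)
        # off-frame CDS noise at frame 1/2 positions
        for shift in (1, 2):
            off_grid = grid + shift
            off_counts = rng.poisson(3.0 * lam * config.offframe_cds_noise / 2.0,
                                     size=off_grid.size)
            _emit(rng, records, gid, off_grid, off_counts, lengths, length_p, offsets)

        # stall pile-up at the penultimate codon (inside the CDS edge zone)
        if config.stall_multiplier > 1.0:
            extra = rng.poisson(3.0 * lam * (config.stall_multiplier - 1.0))
            if extra:
                _emit(rng, records, gid, np.array([model.stop_start - 3]),
                      np.array([extra]), lengths, length_p, offsets)

        # frame-0 adjusted-3'-UTR grid (from the canonical stop to transcript end)
        grid3 = np.arange(model.stop_start, model.length, 3)
        counts3 = rng.poisson(3.0 * lam_utr, size=grid3.size)
        _emit(rng, records, gid, grid3, counts3, lengths, length_p, offsets)
        if config.frame_fidelity < 1.0:
            off_rate = (3.0 * lam_utr
                        * (1.0 - config.frame_fidelity) / config.frame_fidelity / 2.0)
            for shift in (1, 2):
                off_grid = grid3[:-1] + shift
                off_counts = rng.poisson(off_rate, size=off_grid.size)
                _emit(rng, records, gid, off_grid, off_counts,
                      lengths, length_p, offsets)
        if config.stall_multiplier > 1.0:
            rm = locate_extension(model)
            if rm.has_downstream_stop:
                ds = rm.ext[1] - 3  # first nt of the downstream stop (frame 0)
                extra = rng.poisson(3.0 * lam_utr * (config.stall_multiplier - 1.0))
                if extra:
                    _emit(rng, records, gid, np.array([ds]), np.array([extra]),
                          lengths, length_p, offsets)

    return [RawRead(r.transcript_id, r.five_prime, r.length, r.count)
            for r in records]


def simulate_rnaseq(
    models: Mapping[str, TranscriptModel],
    truth: pd.DataFrame,
    config: SyntheticConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene RNA-seq counts: Poisson around abundance × transcript length."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    gids = sorted(models)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=len(gids))
    weights = abundance * np.array([models[g].length for g in gids], dtype=float)
    total = weights.sum()
    expected = (config.rnaseq_depth * weights / total) if total > 0 else weights
    counts = rng.poisson(expected)
    return pd.DataFrame(
        {"gene": gids, "abundance": abundance, "count": counts}
    ).set_index("gene")


# ---------------------------------------------------------------------------
# writers (all plain text; round-trip through the pipeline readers)


def write_fasta_gff3(models: Mapping[str, TranscriptModel],
                     fasta_path: str, gff3_path: str) -> None:
    """One contig per gene (DNA); mRNA/exon/CDS/UTR features in GFF3.

    Genes without experimental UTR annotation get an mRNA covering only the
    CDS — their UTR sequence is present on the contig as flanking sequence,
    exercising the loader's default-length imputation.
    """
    with open(fasta_path, "w") as fa:
        for gid in sorted(models):
            dna = models[gid].seq.replace("U", "T")
            fa.write(f">ctg_{gid}\n")
            for i in range(0, len(dna), 70):
                fa.write(dna[i : i + 70] + "\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for gid in sorted(models):
            m = models[gid]
            ctg = f"ctg_{gid}"
            cds_lo, cds_hi = m.cds_start + 1, m.cds_end  # 1-based inclusive
            if m.utr3_annotated:
                lo, hi = 1, m.length
            else:
                lo, hi = cds_lo, cds_hi
            gff.write(f"{ctg}\tribore\tgene\t{lo}\t{hi}\t.\t+\t.\tID=gene:{gid}\n")
            gff.write(f"{ctg}\tribore\tmRNA\t{lo}\t{hi}\t.\t+\t.\tID={gid};Parent=gene:{gid}\n")
            gff.write(f"{ctg}\tribore\texon\t{lo}\t{hi}\t.\t+\t.\tParent={gid}\n")
            gff.write(f"{ctg}\tribore\tCDS\t{cds_lo}\t{cds_hi}\t.\t+\t0\tParent={gid}\n")
            if m.utr3_annotated:
                if m.utr5_len > 0:
                    gff.write(f"{ctg}\tribore\tfive_prime_UTR\t1\t{m.utr5_len}\t.\t+\t.\tParent={gid}\n")
                if m.utr3_len > 0:
                    gff.write(f"{ctg}\tribore\tthree_prime_UTR\t{m.cds_end + 1}\t{m.length}\t.\t+\t.\tParent={gid}\n")


def write_sam(reads: Sequence[RawRead], models: Mapping[str, TranscriptModel],
              path: str) -> None:
    """Transcriptome SAM; 3' overhang past the transcript end is soft-clipped."""
    with open(path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unknown\n")
        for gid in sorted(models):
            sam.write(f"@SQ\tSN:{gid}\tLN:{models[gid].length}\n")
        i = 0
        for r in reads:
            L = models[r.transcript_id].length
            matched = min(r.length, L - r.five_prime)
            clip = r.length - matched
            cigar = f"{matched}M" + (f"{clip}S" if clip else "")
            for _ in range(r.count):
                sam.write(f"rd{i}\t0\t{r.transcript_id}\t{r.five_prime + 1}\t255"
                          f"\t{cigar}\t*\t0\t0\t{'N' * r.length}\t*\n")
                i += 1


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index_label="gene")


def read_truth_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_dataset(out_dir: str, config: SyntheticConfig,
                  effect_map: Mapping[tuple[str, str], float] | None = None,
                  noise_sd: float | None = None,
                  sam: bool = False) -> dict:
    """Generate and write a complete dataset under one directory.

    Emits genome FASTA + GFF3, footprint reads (TSV and optionally SAM),
    offset table, truth table, RNA-seq abundance table and a JSON manifest.
    """
    from .footprints import write_reads_tsv

    os.makedirs(out_dir, exist_ok=True)
    models, truth = generate_transcriptome(config)
    truth = assign_true_re(truth, effect_map or config.effect_map,
                           config.re_sd if noise_sd is None else noise_sd,
                           baseline=config.re_mean, seed=config.seed + 3)
    reads = simulate_footprints(models, truth, config)
    rna = simulate_rnaseq(models, truth, config)

    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "gff3": os.path.join(out_dir, "annotation.gff3"),
        "reads": os.path.join(out_dir, "footprints.tsv"),
        "offsets": os.path.join(out_dir, "offsets.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "rnaseq": os.path.join(out_dir, "rnaseq.tsv"),
    }
    write_fasta_gff3(models, paths["fasta"], paths["gff3"])
    write_reads_tsv(reads, paths["reads"])
    config.offset_table().to_tsv(paths["offsets"])
    write_truth_tsv(truth, paths["truth"])
    rna.to_csv(paths["rnaseq"], sep="\t", index_label="gene")
    if sam:
        paths["sam"] = os.path.join(out_dir, "footprints.sam")
        write_sam(reads, models, paths["sam"])
    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "cds_read_density": config.cds_read_density,
        "files": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
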