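"""Transcript models, analysis regions and the filtered reference gene set.

Everything downstream works in transcript coordinates (0-based, half-open
intervals).  A transcript is laid out as

    [0, utr5_len) 5'-UTR | [utr5_len, utr5_len+cds_len) CDS | 3'-UTR

where the CDS *includes* its stop codon.  Following the convention of the
modified transcriptome used for P-site analyses, the canonical stop codon is
treated as part of the 3'-UTR for region bookkeeping: ``cds_adj`` is the CDS
minus its stop, and ``utr3_adj`` is the stop codon plus the annotated 3'-UTR.
The "extension" is the 3'-UTR segment from the first nucleotide after the
canonical stop through the first downstream in-frame stop codon; the rest of
the 3'-UTR is the "distal" region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: region labels used throughout the pipeline
REGIONS = ("utr5", "cds", "extension", "distal_utr3")

DEFAULT_UTR5 = 97
DEFAULT_UTR3 = 173


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptModel:
    """One spliced protein-coding transcript and its region geometry."""

    id: str
    seq: str  # RNA alphabet (A/C/G/U)
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr3_annotated: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _to_rna(self.seq))

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def cds_start(self) -> int:
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """End of the annotated CDS (exclusive), stop codon included."""
        return self.utr5_len + self.cds_len

    @property
    def stop_start(self) -> int:
        """First nucleotide of the canonical stop codon."""
        return self.cds_end - 3

    @property
    def stop_codon(self) -> str:
        return self.seq[self.stop_start : self.cds_end]

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start : self.cds_end]

    @property
    def utr3_seq(self) -> str:
        """Annotated 3'-UTR (after the canonical stop codon)."""
        return self.seq[self.cds_end :]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.seq):
            problems.append(
                f"{self.id}: region lengths "
                f"{self.utr5_len}+{self.cds_len}+{self.utr3_len} "
                f"!= sequence length {len(self.seq)}"
            )
        if self.cds_len % 3 != 0:
            problems.append(f"{self.id}: CDS length {self.cds_len} not divisible by 3")
        if self.cds_len < 6:
            problems.append(f"{self.id}: CDS length {self.cds_len} < 6")
        elif self.cds_len % 3 == 0 and self.stop_codon not in STOP_CODONS:
            problems.append(f"{self.id}: CDS does not end in a stop codon ({self.stop_codon})")
        return problems


@dataclass(frozen=True)
class RegionMap:
    """Half-open intervals for one transcript's analysis regions.

    ``cds_adj`` is the annotated CDS minus its stop codon; ``utr3_adj``
    spans the canonical stop codon plus the annotated 3'-UTR; ``ext`` and
    ``distal`` partition the post-stop 3'-UTR.
    """

    id: str
    cds_adj: tuple[int, int]
    utr3_adj: tuple[int, int]
    ext: tuple[int, int]
    distal: tuple[int, int]
    has_downstream_stop: bool
    empty_utr3: bool = False


def locate_extension(model: TranscriptModel, include_downstream_stop: bool = True) -> RegionMap:
    """Scan the post-stop 3'-UTR codon by codon for the first in-frame stop.

    The extension runs from the first nucleotide after the canonical stop
    through (by default) the last nucleotide of the first downstream in-frame
    stop codon.  If no in-frame stop exists within the 3'-UTR the extension
    covers the whole post-stop 3'-UTR and ``has_downstream_stop`` is False.
    """
    cds_adj = (model.cds_start, model.stop_start)
    utr3_adj = (model.stop_start, model.length)
    post_stop = model.cds_end
    if model.utr3_len == 0:
        return RegionMap(model.id, cds_adj, utr3_adj, (post_stop, post_stop),
                         (post_stop, post_stop), False, empty_utr3=True)
    seq = model.seq
    ext_end = None
    for i in range(post_stop, model.length - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            ext_end = i + 3 if include_downstream_stop else i
            break
    if ext_end is None:
        return RegionMap(model.id, cds_adj, utr3_adj, (post_stop, model.length),
                         (model.length, model.length), False)
    return RegionMap(model.id, cds_adj, utr3_adj, (post_stop, ext_end),
                     (ext_end, model.length), True)


def region_of(model: TranscriptModel, regionmap: RegionMap, psite: int,
              stop_in_cds: bool = False) -> str:
    """Label a P-site position as utr5 / cds / extension / distal_utr3.

    By default the canonical stop codon's positions fall on the 3'-UTR side
    and are reported with the extension flank; ``stop_in_cds`` restores the
    standard convention in which the stop codon belongs to the CDS.
    """
    if not 0 <= psite < model.length:
        raise ValueError(f"P-site {psite} out of range for {model.id} (len {model.length})")
    if psite < model.utr5_len:
        return "utr5"
    if stop_in_cds:
        if psite < model.cds_end:
            return "cds"
    else:
        if psite < model.stop_start:
            return "cds"
        if psite < model.cds_end:
            return "extension"  # canonical stop codon -> extension flank
    if psite < regionmap.ext[1]:
        return "extension"
    return "distal_utr3"


def build_reference_set(
    models: Iterable[TranscriptModel],
    overlap_pairs: Sequence[tuple[str, str, int, bool]] = (),
    max_overlap: int = 18,
) -> set[str]:
    """Filtered reference gene set.

    Retains genes with experimentally annotated 3'-UTRs and without a
    same-strand overlap of more than ``max_overlap`` nt with another gene
    (an overlap of exactly ``max_overlap`` nt is retained).
    """
    kept = {m.id for m in models if m.utr3_annotated}
    for id_a, id_b, overlap_nt, same_strand in overlap_pairs:
        if same_strand and overlap_nt > max_overlap:
            kept.discard(id_a)
            kept.discard(id_b)
    return kept


# ---------------------------------------------------------------------------
# loading from GFF3 + FASTA


@dataclass
class ValidationIssue:
    record: str
    message: str


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def load_transcriptome(
    gff3: str,
    fasta: str,
    utr_defaults: tuple[int, int] = (DEFAULT_UTR5, DEFAULT_UTR3),
    utr_table: Mapping[str, tuple[int, int]] | None = None,
) -> tuple[list[TranscriptModel], list[ValidationIssue]]:
    """Build transcript models from a GFF3 annotation over a genome FASTA.

    Exons are spliced in genomic order (reverse-complemented on the minus
    strand) and CDS coordinates are mapped into transcript space.  mRNAs
    without annotated UTRs receive flanking genomic sequence of the default
    lengths (clipped at contig ends) and are flagged ``utr3_annotated=False``.
    An optional per-transcript table of (utr5_len, utr3_len) overrides the
    defaults and counts as experimental annotation.

    Records violating the transcript invariants (CDS not codon-complete, no
    terminal stop codon) are rejected and reported, not silently dropped.
    A CDS referencing a contig absent from the FASTA is a fatal error.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        gff3, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = Fasta(fasta)
    models: list[TranscriptModel] = []
    issues: list[ValidationIssue] = []
    utr_table = dict(utr_table or {})

    mrnas = list(db.features_of_type("mRNA"))
    if not mrnas:  # annotation may use gene records directly
        mrnas = list(db.features_of_type("gene"))
    for mrna in mrnas:
        tid = mrna.id
        cds_parts = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_parts:
            continue
        if mrna.seqid not in genome:
            raise ValueError(f"{tid}: contig {mrna.seqid} absent from FASTA")
        exons = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
        if not exons:
            exons = cds_parts
        has_utr5 = any(True for _ in db.children(mrna, featuretype="five_prime_UTR"))
        has_utr3 = any(True for _ in db.children(mrna, featuretype="three_prime_UTR"))
        strand = mrna.strand
        contig = str(genome[mrna.seqid][:])
        contig_len = len(contig)

        # genomic extent of exons and CDS (1-based inclusive, per GFF3)
        ex_iv = [(e.start, e.end) for e in exons]
        cds_lo = min(c.start for c in cds_parts)
        cds_hi = max(c.end for c in cds_parts)
        cds_len = sum(c.end - c.start + 1 for c in cds_parts)

        tbl = utr_table.get(tid)
        ex_lo, ex_hi = ex_iv[0][0], ex_iv[-1][1]
        annotated = has_utr5 or has_utr3 or ex_lo < cds_lo or ex_hi > cds_hi
        if tbl is not None:
            want5, want3 = tbl
            annotated = True
        elif annotated:
            want5 = want3 = None
        else:
            want5, want3 = utr_defaults
        if want5 is not None:
            # extend terminal exons with flanking genomic sequence
            up, down = (want5, want3) if strand != "-" else (want3, want5)
            new_lo = max(1, ex_lo - up)
            new_hi = min(contig_len, ex_hi + down)
            ex_iv[0] = (new_lo, ex_iv[0][1])
            ex_iv[-1] = (ex_iv[-1][0], new_hi)

        # splice and map CDS extent into transcript coordinates
        parts = [contig[s - 1 : e] for s, e in ex_iv]
        spliced = "".join(parts)

        def g2t(gpos: int) -> int:
            """Genomic (1-based) -> transcript offset on the plus-spliced seq."""
            off = 0
            for s, e in ex_iv:
                if s <= gpos <= e:
                    return off + (gpos - s)
                off += e - s + 1
            raise ValueError(f"{tid}: position {gpos} outside exons")

        try:
            t_lo = g2t(cds_lo)
            t_hi = g2t(cds_hi)
        except ValueError as err:
            issues.append(ValidationIssue(tid, str(err)))
            continue
        if strand == "-":
            spliced = _revcomp(spliced)
            n = len(spliced)
            t_lo, t_hi = n - 1 - t_hi, n - 1 - t_lo
        utr5_len = t_lo
        utr3_len = len(spliced) - (t_hi + 1)

        model = TranscriptModel(
            id=tid,
            seq=spliced,
            utr5_len=utr5_len,
            cds_len=cds_len,
            utr3_len=utr3_len,
            utr3_annotated=annotated,
        )
        problems = model.validate()
        if problems:
            issues.extend(ValidationIssue(tid, p) for p in problems)
        else:
            models.append(model)
    return models, issues


def read_utr_table(path: str) -> dict[str, tuple[int, int]]:
    """TSV with columns transcript_id, utr5_len, utr3_len (header optional)."""
    table = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields[0] in ("", "transcript_id"):
                continue
            table[fields[0]] = (int(fields[1]), int(fields[2]))
    return table


def write_models_tsv(models: Iterable[TranscriptModel], path_or_buf) -> None:
    buf = path_or_buf if hasattr(path_or_buf, "write") else open(path_or_buf, "w")
    try:
        buf.write("id\tlength\tutr5_len\tcds_len\tutr3_len\tutr3_annotated\tstop_codon\n")
        for m in models:
            buf.write(
                f"{m.id}\t{m.length}\t{m.utr5_len}\t{m.cds_len}\t{m.utr3_len}"
                f"\t{int(m.utr3_annotated)}\t{m.stop_codon}\n"
            )
    finally:
        if not hasattr(path_or_buf, "write"):
            buf.close()


def write_regionmaps_tsv(regionmaps: Iterable[RegionMap], path_or_buf) -> None:
    buf = path_or_buf if hasattr(path_or_buf, "write") else open(path_or_buf, "w")
    try:
        buf.write("id\tcds_start\tcds_end\tutr3_start\tutr3_end\text_start\text_end"
                  "\tdistal_start\tdistal_end\thas_downstream_stop\n")
        for r in regionmaps:
            buf.write(
                f"{r.id}\t{r.cds_adj[0]}\t{r.cds_adj[1]}\t{r.utr3_adj[0]}\t{r.utr3_adj[1]}"
                f"\t{r.ext[0]}\t{r.ext[1]}\t{r.distal[0]}\t{r.distal[1]}"
                f"\t{int(r.has_downstream_stop)}\n"
            )
    finally:
        if not hasattr(path_or_buf, "write"):
            buf.close()
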