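"""Per-gene predictor variables: stop-codon context, nascent peptide, 3'-UTR.

The feature set covers (i) the sequence neighbourhood of the canonical stop
codon — the stop itself (nt +1..+3 in the A site), nt −15..−1 upstream and
nt +4..+9 downstream, the P-site and E-site codons/amino acids and the first
in-frame 3'-UTR stop; (ii) physicochemical summaries of the C-terminal
nascent peptide binned into ribosome exit-tunnel regions; (iii) 3'-UTR
descriptors (length, externally predicted structure MFE and distance, helix
fraction); (iv) codon optimality (tAI); and (v) two randomized negative
controls used to calibrate feature-importance baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .transcriptome import RegionMap, TranscriptModel

NT_LEVELS = ("A", "C", "G", "U")
STOP_LEVELS = ("UAA", "UAG", "UGA")

#: exit-tunnel regions as residue ranges counted back from the stop codon
#: (aa 1 = P-site residue, the last residue before the stop)
TUNNEL_REGIONS = {
    "upper": (3, 9),
    "constriction": (10, 12),
    "central": (13, 19),
    "lower": (20, 30),
}

# Residue property assignments (user-overridable). Hydrophobicity classes are
# quartile bins of the Kyte-Doolittle scale.
DEFAULT_PROPERTIES = {
    "charge": {
        "pos": set("KRH"),
        "neg": set("DE"),
        "neu": set("ACFGILMNPQSTVWY"),
    },
    "polarity": {
        "polar": set("STCYNQDEKRH"),
        "nonpolar": set("GAVLIPFMW"),
    },
    "aromatic": {"aromatic": set("FWY"), "nonaromatic": set("ACDEGHIKLMNPQRSTV")},
    "hydrophobicity": {
        "very_hydrophobic": set("IVL"),
        "hydrophobic": set("FCMA"),
        "neutral": set("GTSWYPH"),
        "hydrophilic": set("NDQEKR"),
    },
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def validate_property_tables(tables: Mapping[str, Mapping[str, set]]) -> None:
    """Each property must partition the 20 residues exactly once."""
    for prop, classes in tables.items():
        seen: list[str] = []
        for members in classes.values():
            seen.extend(members)
        if sorted(seen) != sorted(AA20):
            raise ValueError(f"property table {prop!r} does not cover the 20 residues exactly once")


def translate_c_terminus(model: TranscriptModel, n_codons: int = 30) -> str:
    """C-terminal residues, indexed from the peptidyl-transferase end.

    Position 1 of the returned string is the last residue before the stop
    codon (the P-site residue at termination), position 2 the E-site residue,
    and so on.  Genes with fewer than ``n_codons`` sense codons return a
    shorter string.  An internal in-frame stop raises a validation error.
    """
    cds = model.cds_seq[:-3]  # drop the stop codon
    peptide = str(Seq(cds.replace("U", "T")).translate())
    if "*" in peptide:
        raise ValueError(f"{model.id}: internal in-frame stop codon in CDS")
    return peptide[::-1][:n_codons]


def tunnel_property_fractions(
    residue_window: str,
    tables: Mapping[str, Mapping[str, set]] = DEFAULT_PROPERTIES,
) -> dict[str, float]:
    """Class fractions of one tunnel-region residue window.

    Returns NaN fractions for an empty window (gene shorter than the region).
    """
    out = {}
    n = len(residue_window)
    for prop, classes in tables.items():
        for cls, members in classes.items():
            key = f"{prop}_{cls}"
            if n == 0:
                out[key] = math.nan
            else:
                out[key] = sum(1 for aa in residue_window if aa in members) / n
    return out


def extract_sequence_context(model: TranscriptModel, regionmap: RegionMap) -> dict:
    """Nucleotide-level context around the canonical stop codon.

    Numbering: the stop codon occupies nt +1..+3; nt +4 is the first 3'-UTR
    nucleotide after the stop; nt −1 is the last nucleotide of the penultimate
    (P-site) codon.  Positions that run off a short UTR/CDS are NA and the
    gene is flagged.
    """
    seq = model.seq
    stop0 = model.stop_start
    feats: dict = {"stop_codon": model.stop_codon}
    flagged = False
    for k in range(1, 16):  # nt -1 .. -15
        pos = stop0 - k
        if pos < model.cds_start:
            feats[f"nt_m{k}"] = None
            flagged = True
        else:
            feats[f"nt_m{k}"] = seq[pos]
    for k in range(4, 10):  # nt +4 .. +9
        pos = stop0 + (k - 1)
        if pos >= model.length:
            feats[f"nt_p{k}"] = None
            flagged = True
        else:
            feats[f"nt_p{k}"] = seq[pos]
    if regionmap.has_downstream_stop:
        e = regionmap.ext[1]
        feats["first_utr3_stop"] = seq[e - 3 : e]
    else:
        feats["first_utr3_stop"] = "none"
    psite_codon = seq[stop0 - 3 : stop0]
    esite_codon = seq[stop0 - 6 : stop0 - 3] if stop0 - 6 >= model.cds_start else None
    feats["p_site_codon"] = psite_codon if stop0 - 3 >= model.cds_start else None
    feats["e_site_codon"] = esite_codon
    for name in ("p_site", "e_site"):
        codon = feats[f"{name}_codon"]
        feats[f"{name}_aa"] = (
            str(Seq(codon.replace("U", "T")).translate()) if codon else None
        )
    feats["context_flagged"] = flagged or feats["p_site_codon"] is None
    return feats


def gene_tai(cds_codons: Sequence[str], tai: Mapping[str, float]) -> float:
    """Geometric-mean tRNA adaptation index over the CDS sense codons."""
    if not cds_codons:
        raise ValueError("empty codon list")
    logs = []
    for codon in cds_codons:
        codon = codon.upper().replace("T", "U")
        if codon not in tai:
            raise KeyError(f"codon {codon} absent from tAI table")
        logs.append(math.log(tai[codon]))
    return math.exp(sum(logs) / len(logs))


def cds_codons(model: TranscriptModel) -> list[str]:
    cds = model.cds_seq[:-3]
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def add_negative_controls(genes: Sequence[str], seed: int) -> pd.DataFrame:
    """Seeded uniform controls: integer 1..100 and a 4-level factor."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "random_number": rng.integers(1, 101, size=len(genes)),
            "random_factor": rng.choice(list(NT_LEVELS), size=len(genes)),
        },
        index=list(genes),
    )


def attach_external_features(
    df: pd.DataFrame,
    struct_table: pd.DataFrame | None = None,
    helix_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join externally predicted 3'-UTR structure and helix-fraction tables.

    ``struct_table``: gene-indexed with columns mfe (kcal/mol, <= 0) and
    struct_distance (nt); ``helix_table``: gene-indexed helix_fraction in
    [0, 1].  Genes absent from a table get NA.
    """
    out = df.copy()
    if struct_table is not None:
        out["mfe"] = struct_table.reindex(out.index)["mfe"]
        out["struct_distance"] = struct_table.reindex(out.index)["struct_distance"]
    if helix_table is not None:
        hf = helix_table.reindex(out.index)["helix_fraction"]
        bad = hf.dropna()[(hf.dropna() < 0) | (hf.dropna() > 1)]
        if len(bad):
            raise ValueError(f"helix_fraction outside [0,1] for {list(bad.index)[:5]}")
        out["helix_fraction"] = hf
    return out


def build_feature_matrix(
    models: Mapping[str, TranscriptModel],
    regionmaps: Mapping[str, RegionMap],
    seed: int,
    struct_table: pd.DataFrame | None = None,
    helix_table: pd.DataFrame | None = None,
    tai_table: Mapping[str, float] | None = None,
    property_tables: Mapping[str, Mapping[str, set]] = DEFAULT_PROPERTIES,
    n_codons: int = 30,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assemble the gene × feature matrix and its schema.

    Returns ``(matrix, schema)`` where schema maps feature name to
    ``"categorical"`` or ``"numeric"``.  Feature extraction is a pure function
    of (models, tables, seed).
    """
    validate_property_tables(property_tables)
    rows = []
    for gid in sorted(models):
        model = models[gid]
        feats = extract_sequence_context(model, regionmaps[gid])
        try:
            pep = translate_c_terminus(model, n_codons)
        except ValueError:
            pep = ""
            feats["context_flagged"] = True
        for region, (lo, hi) in TUNNEL_REGIONS.items():
            window = pep[lo - 1 : hi]
            for key, val in tunnel_property_fractions(window, property_tables).items():
                feats[f"{region}_{key}"] = val
        feats["utr3_len"] = model.utr3_len
        if tai_table is not None:
            feats["cds_tai"] = gene_tai(cds_codons(model), tai_table)
            psc = feats.get("p_site_codon")
            feats["p_site_tai"] = tai_table.get(psc, math.nan) if psc else math.nan
        feats["gene"] = gid
        rows.append(feats)
    df = pd.DataFrame(rows).set_index("gene")
    df = df.drop(columns=["p_site_codon", "e_site_codon"])
    df = attach_external_features(df, struct_table, helix_table)
    df = df.join(add_negative_controls(list(df.index), seed))

    schema: dict[str, str] = {}
    for col in df.columns:
        if col == "context_flagged":
            schema[col] = "flag"
        elif col.startswith(("nt_m", "nt_p")) or col in (
                "stop_codon", "first_utr3_stop", "p_site_aa", "e_site_aa",
                "random_factor"):
            schema[col] = "categorical"
        else:
            schema[col] = "numeric"
    return df, schema


def write_feature_matrix(df: pd.DataFrame, schema: Mapping[str, str],
                         matrix_path: str, schema_path: str) -> None:
    df.to_csv(matrix_path, sep="\t", index_label="gene")
    with open(schema_path, "w") as fh:
        fh.write("feature\ttype\n")
        for name, kind in schema.items():
            fh.write(f"{name}\t{kind}\n")


def read_feature_matrix(matrix_path: str, schema_path: str) -> tuple[pd.DataFrame, dict[str, str]]:
    df = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    schema = {}
    with open(schema_path) as fh:
        next(fh)
        for line in fh:
            name, kind = line.rstrip("\n").split("\t")
            schema[name] = kind
    return df, schema


def read_tai_table(path: str) -> dict[str, float]:
    """TSV columns: codon, tai. All 61 sense codons must be covered."""
    table = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].lower() == "codon":
                continue
            table[fields[0].upper().replace("T", "U")] = float(fields[1])
    if len(table) < 61:
        raise ValueError(f"tAI table covers only {len(table)} of 61 sense codons")
    return table
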