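"""Context-enrichment statistics for readthrough efficiency.

Four analyses, each emitting long-format tables ready for tile plots:

* group median shifts — for each level of a categorical sequence feature,
  the difference between the level's median log2 RE and the overall sample
  median, with a Wilcoxon rank-sum test of that level's genes against all
  remaining genes;
* High/Low enrichment — χ² goodness-of-fit of level counts in the High or
  Low readthrough group against expected counts from reference-set
  frequencies, Bonferroni-corrected across feature positions, with per-level
  log2 fraction ratios;
* association residuals — χ² test of independence between two categorical
  features with per-cell Pearson residuals (attraction/repulsion);
* Spearman correlations and a pairwise correlation matrix, including derived
  variables such as translation efficiency (ribosome density / expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupShiftCell:
    feature: str
    level: str
    n_genes: int
    delta_median: float
    p_value: float
    significant: bool
    small_group: bool = False  # fewer than 5 genes


def group_median_shifts(
    log2_re: pd.Series,
    feature: pd.Series,
    alpha: float = 0.05,
    variant: str = "rank_sum",
) -> list[GroupShiftCell]:
    """Per-level median shift of log2 RE versus the whole sample.

    ``variant="rank_sum"`` (default) tests each level's genes against all
    remaining genes with a two-sided Wilcoxon rank-sum (Mann-Whitney) test;
    ``variant="signed_rank"`` instead tests the level against the sample
    median with a one-sample signed-rank test.  The reported effect is always
    the level median minus the overall sample median.
    """
    df = pd.DataFrame({"y": log2_re, "level": feature}).dropna()
    df = df[np.isfinite(df["y"])]
    overall = float(df["y"].median())
    cells = []
    for level, sub in df.groupby("level", sort=True, observed=True):
        rest = df.loc[df["level"] != level, "y"]
        if len(sub) == 0:
            continue
        if len(rest) == 0:
            p = 1.0  # the level contains every gene
        elif variant == "rank_sum":
            p = float(stats.mannwhitneyu(sub["y"], rest, alternative="two-sided").pvalue)
        elif variant == "signed_rank":
            diffs = sub["y"] - overall
            diffs = diffs[diffs != 0]
            p = float(stats.wilcoxon(diffs).pvalue) if len(diffs) else 1.0
        else:
            raise ValueError(f"unknown variant {variant!r}")
        cells.append(
            GroupShiftCell(
                feature=str(feature.name or "feature"),
                level=str(level),
                n_genes=len(sub),
                delta_median=float(sub["y"].median()) - overall,
                p_value=p,
                significant=p < alpha,
                small_group=len(sub) < 5,
            )
        )
    return cells


@dataclass
class EnrichmentCell:
    group: str  # "High" or "Low"
    feature: str
    level: str
    n_obs: int
    log2_ratio: float  # nan when zero observation
    p_value: float  # Bonferroni-adjusted, per (group, feature) test
    zero_observation: bool


def high_low_enrichment(
    high_ids: Sequence[str],
    low_ids: Sequence[str],
    reference: pd.Series,
    n_positions_tested: int = 1,
    alpha: float = 0.05,
) -> list[EnrichmentCell]:
    """χ² goodness-of-fit of High/Low level usage against the reference.

    ``reference`` is a categorical feature column indexed by gene over the
    full reference set; High/Low gene ids must be subsets of that index.
    Expected counts come from reference frequencies; the test p-value is
    Bonferroni-multiplied by ``n_positions_tested`` (the number of feature
    positions in the heatmap).  Levels absent from a group are flagged
    ``zero_observation`` (no log2 ratio).
    """
    ref = reference.dropna().astype(str)
    levels = sorted(ref.unique())
    ref_frac = ref.value_counts(normalize=True).reindex(levels).fillna(0.0)
    feature_name = str(reference.name or "feature")
    cells = []
    for group_name, ids in (("High", high_ids), ("Low", low_ids)):
        obs_counts = ref.reindex([i for i in ids if i in ref.index]).value_counts()
        obs = obs_counts.reindex(levels).fillna(0).astype(int)
        n = int(obs.sum())
        expected = ref_frac.to_numpy() * n
        usable = expected > 0
        if usable.sum() >= 2 and n > 0:
            chi = stats.chisquare(obs.to_numpy()[usable], expected[usable])
            p_adj = min(1.0, float(chi.pvalue) * n_positions_tested)
        else:
            p_adj = math.nan
        for lev in levels:
            n_obs = int(obs[lev])
            frac = n_obs / n if n else 0.0
            zero = n_obs == 0
            ratio = math.nan if zero or ref_frac[lev] == 0 else math.log2(frac / ref_frac[lev])
            cells.append(
                EnrichmentCell(group_name, feature_name, str(lev), n_obs,
                               ratio, p_adj, zero)
            )
    return cells


@dataclass
class ResidualTable:
    row_feature: str
    col_feature: str
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame  # Pearson residuals (O-E)/sqrt(E)
    p_value: float
    small_sample: bool  # any expected cell < 5


def association_residuals(
    feat_a: pd.Series,
    feat_b: pd.Series,
) -> ResidualTable:
    """χ² independence test between two categorical features.

    Positive residuals indicate attraction (the level pair co-occurs more
    often than expected under independence), negative residuals repulsion.
    """
    df = pd.DataFrame({"a": feat_a.astype(str), "b": feat_b.astype(str)}).dropna()
    table = pd.crosstab(df["a"], df["b"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (single row or column)")
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    residuals = (table - expected) / np.sqrt(expected)
    return ResidualTable(
        row_feature=str(feat_a.name or "a"),
        col_feature=str(feat_b.name or "b"),
        observed=table,
        expected=expected,
        residuals=residuals,
        p_value=float(p),
        small_sample=bool((expected.to_numpy() < 5).any()),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector; Spearman undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def translation_efficiency(ribo_density: pd.Series, expression: pd.Series) -> pd.Series:
    """Ribosome density divided by gene expression level, aligned by gene."""
    te = ribo_density / expression.reindex(ribo_density.index)
    te[~np.isfinite(te)] = np.nan
    return te.rename("translation_efficiency")


def correlation_matrix(variables: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman ρ matrix (symmetric, unit diagonal)."""
    cols = list(variables.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            try:
                rho, _ = spearman(variables[a], variables[b])
            except ValueError:
                rho = np.nan
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def shifts_to_frame(cells: Sequence[GroupShiftCell]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cells])


def enrichment_to_frame(cells: Sequence[EnrichmentCell]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cells])
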