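"""RNA-affinity-chromatography proteomics enrichment analysis.

Background-corrected enrichment per protein and substrate is
(NSC_substrate - NSC_APT) / NSC_NE, i.e. the aptamer-only background is
subtracted and the result scaled to the protein's abundance in the input
nuclear extract.  Downstream: positive/negative tallies over a protein set,
row Z-scoring and hierarchical clustering for heatmaps, and DIA-style
replicate differential analysis with the loose (|L2FC| > 0.2, p < 0.01) and
stringent (|L2FC| >= 0.7, p < 0.01) filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io_formats import SpectralCountTable
from .stats_core import student_t_test

__all__ = [
    "EnrichmentResult",
    "ProteinSets",
    "background_corrected_enrichment",
    "pos_neg_counts",
    "row_zscore",
    "hierarchical_cluster_order",
    "differential_protein_abundance",
    "classify_enriched_sets",
]


@dataclass
class EnrichmentResult:
    """Protein x substrate background-corrected enrichment matrix.

    ``excluded`` lists proteins dropped because their nuclear-extract value
    was zero or missing (the denominator of the correction).
    """

    matrix: pd.DataFrame
    excluded: pd.DataFrame  # protein_id, reason


@dataclass(frozen=True)
class ProteinSets:
    """Membership lists: early spliceosome / 17S U2 (E/U2) and other RBPs."""

    eu2_members: frozenset[str]
    rbp_members: frozenset[str]

    def category(self, protein: str) -> str:
        if protein in self.eu2_members:
            return "E/U2"
        if protein in self.rbp_members:
            return "other RBP"
        return "other"


def background_corrected_enrichment(table: SpectralCountTable) -> EnrichmentResult:
    """(NSC_substrate - NSC_APT) / NSC_NE per protein and substrate.

    Requires exactly one NE and one APT column; proteins whose NE value is
    zero or missing are excluded with a reason (the correction is undefined
    for them).  Missing substrate or APT cells propagate to NaN.
    """
    ne_cols = table.columns_with_role("NE")
    apt_cols = table.columns_with_role("APT")
    if len(apt_cols) != 1:
        raise ValueError(f"need exactly one APT column, got {apt_cols}")
    if len(ne_cols) != 1:
        raise ValueError(f"need exactly one NE column, got {ne_cols}")
    substrates = table.columns_with_role("substrate")
    if not substrates:
        raise ValueError("no substrate columns")
    ne = table.data[ne_cols[0]]
    apt = table.data[apt_cols[0]]
    usable = ne.notna() & (ne > 0)
    excluded = pd.DataFrame(
        {
            "protein_id": ne.index[~usable],
            "reason": [
                "missing_NE" if pd.isna(v) else "zero_NE"
                for v in ne[~usable]
            ],
        }
    )
    sub = table.data.loc[usable, substrates]
    matrix = sub.sub(apt[usable], axis=0).div(ne[usable], axis=0)
    return EnrichmentResult(matrix=matrix, excluded=excluded)


def pos_neg_counts(
    enrichment: EnrichmentResult | pd.DataFrame, members: Sequence[str]
) -> pd.DataFrame:
    """Per-substrate sign tallies over a protein set.

    Restricted to set members with a positive enrichment in at least one
    substrate (the heatmap inclusion rule).  Zeros count as neither positive
    nor negative and are reported in their own column; per substrate,
    n_pos + n_neg + n_zero equals the number of included members quantified
    there.
    """
    matrix = enrichment.matrix if isinstance(enrichment, EnrichmentResult) else enrichment
    present = [p for p in matrix.index if p in set(members)]
    sub = matrix.loc[present]
    included = sub.index[(sub > 0).any(axis=1)]
    sub = sub.loc[included]
    return pd.DataFrame(
        {
            "n_pos": (sub > 0).sum(),
            "n_neg": (sub < 0).sum(),
            "n_zero": (sub == 0).sum(),
            "n_missing": sub.isna().sum(),
        }
    )


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, population SD 1.

    Constant rows (SD 0) become all-zero with a warning instead of NaN.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to Z-score rows")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=0)
    flat = sds == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) set to zero", RuntimeWarning,
            stacklevel=2,
        )
    safe_sds = sds.replace(0, 1.0)
    z = matrix.sub(means, axis=0).div(safe_sds, axis=0)
    z.loc[flat] = 0.0
    return z


def hierarchical_cluster_order(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "average",
    cluster_columns: bool = True,
) -> tuple[list[str], list[str]]:
    """Leaf orders from average-linkage hierarchical clustering.

    Rows (and optionally columns) are sorted lexicographically by id before
    linkage so that equal-height merges resolve deterministically; the
    returned orders are therefore a pure function of the matrix values and
    ids, not of input row order.
    """
    if matrix.isna().any().any():
        raise ValueError("clustered submatrix must have no missing values")

    def order(df: pd.DataFrame) -> list[str]:
        df = df.sort_index()
        if len(df) < 2:
            return list(df.index)
        z = linkage(pdist(df.values, metric=distance), method=linkage_method)
        return [df.index[i] for i in leaves_list(z)]

    rows = order(matrix)
    cols = order(matrix.T) if cluster_columns else list(matrix.columns)
    return rows, cols


def differential_protein_abundance(
    quant: SpectralCountTable,
    group_num: str,
    group_den: str,
    sets: ProteinSets | None = None,
    alpha: float = 0.01,
    loose_lfc: float = 0.2,
    stringent_lfc: float = 0.7,
    adjust: bool = False,
    pooled: bool = True,
) -> pd.DataFrame:
    """Replicate-level differential protein abundance, numerator vs denominator.

    Proteins with any missing or zero value in either replicate group are
    excluded (no imputation).  Values are log2-transformed; log2FC is the
    difference of group means on the log scale and p comes from a two-sample
    t-test on the log values.  Flags: ``passes_loose`` (|L2FC| > loose_lfc,
    p < alpha, strict) and ``passes_stringent`` (|L2FC| >= stringent_lfc,
    p < alpha).  ``adjust=True`` applies Benjamini-Hochberg to the p-values
    before flagging.
    """
    groups = quant.replicate_groups()
    for g in (group_num, group_den):
        if g not in groups:
            raise ValueError(f"unknown replicate group {g!r}")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has < 2 replicate columns")
    num_cols, den_cols = groups[group_num], groups[group_den]
    sub = quant.data[num_cols + den_cols]
    ok = sub.notna().all(axis=1) & (sub > 0).all(axis=1)
    rows = []
    for protein in sub.index[ok]:
        num = np.log2(sub.loc[protein, num_cols].astype(float).values)
        den = np.log2(sub.loc[protein, den_cols].astype(float).values)
        res = student_t_test(list(num), list(den), pooled=pooled)
        rows.append(
            {
                "protein_id": protein,
                "log2fc": float(num.mean() - den.mean()),
                "p_value": res.p_value,
                "category": sets.category(protein) if sets else "other",
            }
        )
    df = pd.DataFrame(
        rows, columns=["protein_id", "log2fc", "p_value", "category"]
    )
    df.attrs["n_excluded_missing"] = int((~ok).sum())
    if df.empty:
        df["passes_loose"] = pd.Series(dtype=bool)
        df["passes_stringent"] = pd.Series(dtype=bool)
        return df
    pvals = df["p_value"].values
    if adjust:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank, i in enumerate(order[::-1]):
            k = m - rank
            prev = min(prev, pvals[i] * m / k)
            adj[i] = prev
        pvals = adj
        df["p_adjusted"] = adj
    df["passes_loose"] = (df["log2fc"].abs() > loose_lfc) & (pvals < alpha)
    df["passes_stringent"] = (df["log2fc"].abs() >= stringent_lfc) & (pvals < alpha)
    return df


def classify_enriched_sets(rows: pd.DataFrame) -> dict[str, int]:
    """Tallies of stringent-flagged proteins by sign and set membership.

    Keys: enriched_eu2 / enriched_rbp (log2FC > 0) and depleted_eu2 /
    depleted_rbp (log2FC < 0); uncategorized ("other") proteins are counted
    under enriched_other / depleted_other so the totals conserve.
    """
    counts = {
        "enriched_eu2": 0,
        "enriched_rbp": 0,
        "enriched_other": 0,
        "depleted_eu2": 0,
        "depleted_rbp": 0,
        "depleted_other": 0,
    }
    if rows.empty:
        return counts
    tag = {"E/U2": "eu2", "other RBP": "rbp", "other": "other"}
    for row in rows.loc[rows["passes_stringent"]].itertuples(index=False):
        side = "enriched" if row.log2fc > 0 else "depleted"
        counts[f"{side}_{tag[row.category]}"] += 1
    return counts
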