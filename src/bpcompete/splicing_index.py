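"""Intron-centric splicing quantification from class-labeled counts.

The central index is percent unspliced = 100 * unspliced/(unspliced+spliced)
per gene and sample, compared between an induced and a control condition by
an unpaired Student t-test on per-replicate values (cutoffs: base mean > 100,
p < 0.1 by default).  Also provides per-class log2 fold-change summaries of
transcript abundance and the 2^-dCt relative-abundance calculator used for
reporter qPCR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClassedCountMatrix
from .stats_core import TestResult, log2_fold_change, mann_whitney_u, student_t_test

__all__ = [
    "percent_unspliced",
    "base_mean",
    "splicing_change_table",
    "SplicingChangeResult",
    "class_abundance_summary",
    "ClassAbundanceSummary",
    "relative_abundance_ddct",
]


def percent_unspliced(unspliced_count: float, spliced_count: float) -> float:
    """100 * unspliced / (unspliced + spliced); NaN when both are zero."""
    if unspliced_count < 0 or spliced_count < 0:
        raise ValueError("counts must be non-negative")
    total = unspliced_count + spliced_count
    if total == 0:
        return float("nan")
    return 100.0 * unspliced_count / total


def base_mean(counts_for_gene_across_all_samples: Sequence[float]) -> float:
    """Arithmetic mean of gene-level counts (unspliced + spliced) per sample."""
    arr = np.asarray(list(counts_for_gene_across_all_samples), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one sample")
    return float(arr.mean())


@dataclass
class SplicingChangeResult:
    """Per-gene splicing-change table plus the genes excluded and why."""

    table: pd.DataFrame
    excluded: pd.DataFrame  # columns: gene_id, reason


def _gene_class_counts(matrix: ClassedCountMatrix) -> dict[str, dict[str, pd.Series]]:
    """gene -> class -> per-sample summed counts (over that gene's rows)."""
    out: dict[str, dict[str, pd.Series]] = {}
    for transcript in matrix.data.index:
        gene = matrix.genes[transcript]
        cls = matrix.classes[transcript]
        row = matrix.data.loc[transcript]
        bucket = out.setdefault(gene, {})
        bucket[cls] = bucket[cls] + row if cls in bucket else row.copy()
    return out


def splicing_change_table(
    matrix: ClassedCountMatrix,
    control_ids: Sequence[str],
    induced_ids: Sequence[str],
    alpha: float = 0.1,
    min_base_mean: float = 100.0,
    exclude_genes: Sequence[str] = (),
    pooled: bool = True,
) -> SplicingChangeResult:
    """Differential percent-unspliced analysis, one row per tested gene.

    Genes must carry both an unspliced and a spliced row; the expression
    filter keeps genes with base mean (unspliced+spliced over *all* given
    samples) strictly above ``min_base_mean``.  A gene with an undefined
    percent-unspliced (0 + 0 counts) in any replicate is excluded with a
    reason rather than imputed.  ``exclude_genes`` drops e.g. genes whose
    intron is not spliceosomal.
    """
    control_ids, induced_ids = list(control_ids), list(induced_ids)
    if len(control_ids) < 2 or len(induced_ids) < 2:
        raise ValueError("need >= 2 replicates per condition")
    all_ids = control_ids + induced_ids
    missing_cols = set(all_ids) - set(matrix.data.columns)
    if missing_cols:
        raise ValueError(f"unknown sample ids: {sorted(missing_cols)}")

    per_gene = _gene_class_counts(matrix)
    rows, excluded = [], []
    for gene in sorted(per_gene):
        classes = per_gene[gene]
        if "unspliced" not in classes or "spliced" not in classes:
            continue  # intronless or partially annotated gene: not testable
        if gene in exclude_genes:
            excluded.append({"gene_id": gene, "reason": "excluded_by_list"})
            continue
        unspl, spl = classes["unspliced"], classes["spliced"]
        totals = (unspl + spl)[all_ids]
        bm = base_mean(totals)
        if not bm > min_base_mean:
            excluded.append({"gene_id": gene, "reason": "low_base_mean"})
            continue
        pu = {
            s: percent_unspliced(float(unspl[s]), float(spl[s])) for s in all_ids
        }
        if any(np.isnan(v) for v in pu.values()):
            excluded.append({"gene_id": gene, "reason": "undefined_percent_unspliced"})
            continue
        ctrl = [pu[s] for s in control_ids]
        ind = [pu[s] for s in induced_ids]
        res = student_t_test(ind, ctrl, pooled=pooled)
        delta = float(np.mean(ind) - np.mean(ctrl))
        rows.append(
            {
                "gene_id": gene,
                **{f"pu_{s}": pu[s] for s in all_ids},
                "mean_control": float(np.mean(ctrl)),
                "mean_induced": float(np.mean(ind)),
                "delta_percent_unspliced": delta,
                "base_mean": bm,
                "t_statistic": res.statistic,
                "p_value": res.p_value,
                "significant": bool(res.p_value < alpha),
                "direction": "increase" if delta >= 0 else "decrease",
            }
        )
    table = pd.DataFrame(rows)
    return SplicingChangeResult(
        table=table,
        excluded=pd.DataFrame(excluded, columns=["gene_id", "reason"]),
    )


@dataclass
class ClassAbundanceSummary:
    """Per-transcript log2FC values and pairwise between-class comparisons."""

    per_transcript: pd.DataFrame  # transcript_id, class, gene_id, log2fc
    pairwise: dict[tuple[str, str], TestResult]
    n_excluded: int


def class_abundance_summary(
    matrix: ClassedCountMatrix,
    control_ids: Sequence[str],
    induced_ids: Sequence[str],
    min_tpm: float = 0.2,
    pseudocount: float = 0.01,
) -> ClassAbundanceSummary:
    """Per-class transcript log2FC distributions, compared by Mann-Whitney U.

    Transcripts below ``min_tpm`` in every sample are excluded.  log2FC is
    mean(induced) vs mean(control) with a pseudocount.  Classes with fewer
    than 2 surviving transcripts are skipped from pairwise comparison with a
    warning.
    """
    control_ids, induced_ids = list(control_ids), list(induced_ids)
    all_ids = control_ids + induced_ids
    data = matrix.data[all_ids]
    keep = (data > min_tpm).any(axis=1)
    n_excluded = int((~keep).sum())
    kept = data.loc[keep]
    lfc = [
        log2_fold_change(
            float(kept.loc[t, induced_ids].mean()),
            float(kept.loc[t, control_ids].mean()),
            pseudocount,
        )
        for t in kept.index
    ]
    per_transcript = pd.DataFrame(
        {
            "transcript_id": kept.index,
            "class": matrix.classes.loc[kept.index].values,
            "gene_id": matrix.genes.loc[kept.index].values,
            "log2fc": lfc,
        }
    )
    pairwise: dict[tuple[str, str], TestResult] = {}
    classes = ["unspliced", "spliced", "intronless"]
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1 :]:
            v1 = per_transcript.loc[per_transcript["class"] == c1, "log2fc"]
            v2 = per_transcript.loc[per_transcript["class"] == c2, "log2fc"]
            if len(v1) < 2 or len(v2) < 2:
                warnings.warn(
                    f"skipping {c1} vs {c2}: fewer than 2 transcripts survive",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            pairwise[(c1, c2)] = mann_whitney_u(v1.tolist(), v2.tolist())
    return ClassAbundanceSummary(per_transcript, pairwise, n_excluded)


def relative_abundance_ddct(
    ct_target: Mapping[str, float],
    ct_reference: Mapping[str, float],
    reference_group_ids: Sequence[str],
) -> pd.DataFrame:
    """Reporter abundance from qPCR cycle thresholds.

    Per sample: dCt = Ct_target - Ct_reference, relative abundance 2^-dCt,
    then normalized so the reference group (e.g. the wild-type reporter)
    averages to 1.  Samples with a missing Ct are dropped with a warning.
    Returns a frame indexed by sample with columns delta_ct, rel_abundance,
    normalized.
    """
    if not len(reference_group_ids):
        raise ValueError("reference group must be non-empty")
    samples = []
    for s in ct_target:
        tgt, ref = ct_target.get(s), ct_reference.get(s)
        if tgt is None or ref is None or np.isnan(tgt) or np.isnan(ref):
            warnings.warn(f"sample {s}: missing Ct, dropped", RuntimeWarning,
                          stacklevel=2)
            continue
        samples.append((s, float(tgt) - float(ref)))
    if not samples:
        raise ValueError("no samples with complete Ct values")
    df = pd.DataFrame(samples, columns=["sample", "delta_ct"]).set_index("sample")
    df["rel_abundance"] = 2.0 ** (-df["delta_ct"])
    ref_ids = [s for s in reference_group_ids if s in df.index]
    if not ref_ids:
        raise ValueError("no reference-group sample survived Ct filtering")
    norm = df.loc[ref_ids, "rel_abundance"].mean()
    df["normalized"] = df["rel_abundance"] / norm
    return df
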