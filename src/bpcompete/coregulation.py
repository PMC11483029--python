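"""Two-contrast alternative-splicing co-regulation analysis.

Works on per-contrast event frames (columns event_id, event_type, gene_id,
dpsi, mv) as produced by :func:`bpcompete.io_formats.events_to_frame`.
Significance cutoffs follow the strict inequalities of the printed rules:
|dPSI| > 10 and MVdPSI95 > 0 for single-contrast significance; co-regulated
events need |dPSI| > 10 in either contrast and MVdPSI95 > 0 in both.
Control events are expressed (base mean > 100) but unchanged in both
contrasts (|dPSI| < 1, MVdPSI95 = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stats_core import TestResult, mann_whitney_u

__all__ = [
    "QUADRANT_LABELS",
    "filter_significant",
    "coregulated_events",
    "classify_quadrant",
    "quadrant_counts",
    "QuadrantCounts",
    "dpsi_distribution_compare",
    "select_control_events",
]

QUADRANT_LABELS = ("upA_downB", "upA_upB", "downA_downB", "downA_upB")

_EVENT_COLS = {"event_id", "dpsi", "mv"}


def _check_frame(df: pd.DataFrame, name: str) -> None:
    missing = _EVENT_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{name} lacks columns {sorted(missing)}")


def filter_significant(
    events: pd.DataFrame, dpsi_min: float = 10.0, mv_min: float = 0.0
) -> pd.DataFrame:
    """Events with |dPSI| > dpsi_min AND MVdPSI95 > mv_min (both strict)."""
    _check_frame(events, "events")
    mask = (events["dpsi"].abs() > dpsi_min) & (events["mv"] > mv_min)
    return events.loc[mask].reset_index(drop=True)


def coregulated_events(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    dpsi_min: float = 10.0,
) -> pd.DataFrame:
    """Events changing in either contrast and confidently measured in both.

    Kept iff (|dPSI_A| > dpsi_min OR |dPSI_B| > dpsi_min) AND MV_A > 0 AND
    MV_B > 0.  Events present in only one table are excluded; their count is
    recorded in ``DataFrame.attrs["n_unmatched"]``.
    """
    _check_frame(table_a, "table_a")
    _check_frame(table_b, "table_b")
    merged = table_a.merge(
        table_b[["event_id", "dpsi", "mv"]],
        on="event_id",
        how="inner",
        suffixes=("_a", "_b"),
    )
    n_unmatched = (len(table_a) - len(merged)) + (len(table_b) - len(merged))
    mask = (
        ((merged["dpsi_a"].abs() > dpsi_min) | (merged["dpsi_b"].abs() > dpsi_min))
        & (merged["mv_a"] > 0)
        & (merged["mv_b"] > 0)
    )
    out = merged.loc[mask].reset_index(drop=True)
    out.attrs["n_unmatched"] = int(n_unmatched)
    return out


def classify_quadrant(dpsi_a: float, dpsi_b: float) -> str | None:
    """Sign-pair quadrant label; None when either dPSI is exactly zero."""
    if dpsi_a == 0 or dpsi_b == 0:
        return None
    if dpsi_a > 0:
        return "upA_upB" if dpsi_b > 0 else "upA_downB"
    return "downA_upB" if dpsi_b > 0 else "downA_downB"


@dataclass
class QuadrantCounts:
    """Counts and fractions per quadrant, plus zero-dPSI events set aside."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_unclassified: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def quadrant_counts(coregulated: pd.DataFrame) -> QuadrantCounts:
    """Tally coregulated events (columns dpsi_a, dpsi_b) into quadrants."""
    counts = {q: 0 for q in QUADRANT_LABELS}
    unclassified = 0
    for da, db in zip(coregulated.get("dpsi_a", []), coregulated.get("dpsi_b", [])):
        label = classify_quadrant(float(da), float(db))
        if label is None:
            unclassified += 1
        else:
            counts[label] += 1
    total = sum(counts.values())
    fractions = {
        q: (counts[q] / total if total else 0.0) for q in QUADRANT_LABELS
    }
    return QuadrantCounts(counts, fractions, unclassified)


def dpsi_distribution_compare(
    table_a: pd.DataFrame, table_b: pd.DataFrame, event_type: str
) -> TestResult:
    """Mann-Whitney U on the dPSI distributions of one event type.

    Both tables are expected to be pre-filtered by :func:`filter_significant`.
    """
    for name, df in (("table_a", table_a), ("table_b", table_b)):
        _check_frame(df, name)
        if "event_type" not in df.columns:
            raise ValueError(f"{name} lacks event_type column")
    xs = table_a.loc[table_a["event_type"] == event_type, "dpsi"].tolist()
    ys = table_b.loc[table_b["event_type"] == event_type, "dpsi"].tolist()
    if not xs or not ys:
        raise ValueError(f"no {event_type!r} events in one of the tables")
    return mann_whitney_u(xs, ys)


def select_control_events(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series,
    n: int = 1000,
    dpsi_max: float = 1.0,
    min_base_mean: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expressed-but-unchanged control events, sampled without replacement.

    Eligible iff base mean > ``min_base_mean`` (keyed by gene in
    ``expression``), |dPSI| < ``dpsi_max`` in both contrasts, and MVdPSI95
    exactly 0 in both.  If fewer than ``n`` events are eligible, all are
    returned with a warning.
    """
    _check_frame(table_a, "table_a")
    _check_frame(table_b, "table_b")
    expr = pd.Series(dict(expression)) if not isinstance(expression, pd.Series) else expression
    merged = table_a.merge(
        table_b[["event_id", "dpsi", "mv"]],
        on="event_id",
        how="inner",
        suffixes=("_a", "_b"),
    )
    bm = merged["gene_id"].map(expr)
    eligible = merged.loc[
        (bm > min_base_mean)
        & (merged["dpsi_a"].abs() < dpsi_max)
        & (merged["dpsi_b"].abs() < dpsi_max)
        & (merged["mv_a"] == 0)
        & (merged["mv_b"] == 0)
    ].reset_index(drop=True)
    if len(eligible) <= n:
        if len(eligible) < n:
            warnings.warn(
                f"only {len(eligible)} eligible control events (< {n}); "
                "returning all",
                RuntimeWarning,
                stacklevel=2,
            )
        return eligible
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(eligible), size=n, replace=False))
    return eligible.iloc[idx].reset_index(drop=True)
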