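"""Time-course differential-expression calling and set logic.

Consumes DESeq2-style result tables (one row per gene x tissue x timepoint
contrast against the 0 h control) and applies the strict thresholds
adjusted p < 0.05 and |log2 fold-change| > 1. Downstream utilities count
calls per contrast, intersect the per-timepoint DEG sets (Venn regions),
classify genes as short-acting (differential at 6 or 12 h) or long-acting
(differential at 24 or 48 h), and find genes differential in both tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TIMEPOINTS = (6, 12, 24, 48)
SHORT_ACTING_TIMEPOINTS = (6, 12)
LONG_ACTING_TIMEPOINTS = (24, 48)

REQUIRED_COLUMNS = ("gene_id", "tissue", "timepoint", "log2_fold_change", "adjusted_p")


def call_degs(
    records: pd.DataFrame,
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Classify every record as up, down or none under strict thresholds.

    up   <=> adjusted_p < padj_cut and log2FC >  lfc_cut
    down <=> adjusted_p < padj_cut and log2FC < -lfc_cut

    Boundary rows (equality) and rows with missing adjusted p are 'none';
    a missing adjusted p is the usual independent-filtering NA and is
    treated as non-significant. ``columns`` remaps nonstandard headers,
    e.g. ``{"log2_fold_change": "log2FoldChange", "adjusted_p": "padj"}``.
    """
    if padj_cut <= 0 or lfc_cut <= 0:
        raise ValueError("thresholds must be positive")
    df = records.rename(
        columns={v: k for k, v in (columns or {}).items()}
    ).copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    bad = df.index[
        df["adjusted_p"].notna()
        & ((df["adjusted_p"] < 0) | (df["adjusted_p"] > 1))
    ]
    if len(bad):
        raise ValueError(f"adjusted_p outside [0, 1] in rows {list(bad[:5])}")

    lfc = df["log2_fold_change"].to_numpy(dtype=float)
    padj = df["adjusted_p"].to_numpy(dtype=float)  # NaN where missing
    sig = padj < padj_cut  # NaN compares False
    direction = np.where(
        sig & (lfc > lfc_cut), "up", np.where(sig & (lfc < -lfc_cut), "down", "none")
    )
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["direction"] = direction
    return out


def _check_unique(calls: pd.DataFrame) -> None:
    dup = calls.duplicated(subset=["gene_id", "tissue", "timepoint"])
    if dup.any():
        first = calls.loc[dup, ["gene_id", "tissue", "timepoint"]].iloc[0]
        raise ValueError(
            "duplicate gene within a contrast: "
            f"{tuple(first)} appears more than once"
        )


def count_by_contrast(calls: pd.DataFrame) -> pd.DataFrame:
    """Per tissue x timepoint counts of up-, down- and total regulated genes."""
    _check_unique(calls)
    grouped = calls.groupby(["tissue", "timepoint"], sort=True)
    rows = []
    for (tissue, tp), g in grouped:
        n_up = int((g["direction"] == "up").sum())
        n_down = int((g["direction"] == "down").sum())
        rows.append(
            {
                "tissue": tissue,
                "timepoint": tp,
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_up + n_down,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VennCounts:
    """Disjoint region counts over the per-timepoint DEG sets of one tissue."""

    timepoints: tuple
    #: maps a frozenset of timepoints (the exact membership pattern) to the
    #: number of genes DEG at exactly those timepoints; 2^k - 1 regions.
    regions: Mapping[frozenset, int]
    union_size: int
    full_intersection: int

    def intersection(self, timepoints: Iterable) -> int:
        """Genes DEG at *at least* the given timepoints (k-way intersection)."""
        want = frozenset(timepoints)
        return sum(n for patt, n in self.regions.items() if want <= patt)


def intersect_contrasts(
    calls: pd.DataFrame,
    tissue: str,
    timepoints: Sequence = DEFAULT_TIMEPOINTS,
) -> VennCounts:
    """Venn decomposition of one tissue's DEG sets across timepoints."""
    sub = calls[calls["tissue"] == tissue]
    unknown = set(sub["timepoint"]) - set(timepoints)
    if unknown:
        raise ValueError(f"unknown timepoints in calls: {sorted(unknown)}")
    sets = {
        tp: set(sub.loc[(sub["timepoint"] == tp) & (sub["direction"] != "none"), "gene_id"])
        for tp in timepoints
    }
    universe = set().union(*sets.values())
    regions = {
        frozenset(patt): 0
        for r in range(1, len(timepoints) + 1)
        for patt in combinations(timepoints, r)
    }
    for gene in universe:
        patt = frozenset(tp for tp in timepoints if gene in sets[tp])
        regions[patt] += 1
    return VennCounts(
        timepoints=tuple(timepoints),
        regions=regions,
        union_size=len(universe),
        full_intersection=regions[frozenset(timepoints)],
    )


def classify_temporal(
    calls: pd.DataFrame,
    short_timepoints: Sequence = SHORT_ACTING_TIMEPOINTS,
    long_timepoints: Sequence = LONG_ACTING_TIMEPOINTS,
) -> pd.DataFrame:
    """Short-/long-acting flags per gene x tissue.

    A gene is short-acting in a tissue if it is differential (either
    direction) at any early timepoint (6 or 12 h), long-acting if
    differential at any late timepoint (24 or 48 h); both flags may hold,
    and a gene differential nowhere gets neither. Classes are per-tissue —
    the two tissues respond on different schedules and are never pooled.
    """
    deg = calls[calls["direction"] != "none"]
    keys = calls.loc[:, ["gene_id", "tissue"]].drop_duplicates().reset_index(drop=True)
    short_set = set(
        map(tuple, deg.loc[deg["timepoint"].isin(short_timepoints), ["gene_id", "tissue"]].itertuples(index=False))
    )
    long_set = set(
        map(tuple, deg.loc[deg["timepoint"].isin(long_timepoints), ["gene_id", "tissue"]].itertuples(index=False))
    )
    pairs = list(keys.itertuples(index=False, name=None))
    keys["short_acting"] = [p in short_set for p in pairs]
    keys["long_acting"] = [p in long_set for p in pairs]
    return keys


def cross_tissue_overlap(
    leaf_calls: pd.DataFrame, rhizome_calls: pd.DataFrame
) -> set[str]:
    """Genes differential at >= 1 timepoint in each of the two tissues."""
    leaf = set(leaf_calls.loc[leaf_calls["direction"] != "none", "gene_id"])
    rhiz = set(rhizome_calls.loc[rhizome_calls["direction"] != "none", "gene_id"])
    return leaf & rhiz
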