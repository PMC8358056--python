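"""Fuzzy membership-function comprehensive evaluation of cultivars.

Each physiological index column is min-max normalised to a membership degree
in [0, 1]; for indices where *smaller* is better (membrane-damage markers
such as REC and MDA) the degree is reversed, U = 1 - (x - min)/(max - min).
A cultivar's composite drought-resistance score is the arithmetic mean of
its membership degrees across indices, and cultivars are ranked by that
mean. Ranking always uses unrounded scores; display rounding (half-up) is
kept separate so that ordering never depends on the reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"

#: Larger is favorable for pigment content, SOD activity and the osmotic
#: solutes; smaller is favorable for the membrane-damage indicators.
DEFAULT_DIRECTIONS: Mapping[str, str] = {
    "Chl": POSITIVE,
    "REC": NEGATIVE,
    "SOD": POSITIVE,
    "MDA": NEGATIVE,
    "SP": POSITIVE,
    "Pro": POSITIVE,
}


class DegenerateColumnError(ValueError):
    """An index column is constant, so min-max membership is undefined."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as spreadsheet-style reports do.

    Uses the shortest decimal representation of the float so that e.g.
    0.675 rounds to 0.68 rather than falling to the binary neighbour.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def membership_degree(x: float, x_min: float, x_max: float, direction: str) -> float:
    """Min-max membership of one observation within its index column."""
    if direction not in (POSITIVE, NEGATIVE):
        raise ValueError(f"direction must be positive|negative, got {direction!r}")
    if x_max <= x_min:
        raise DegenerateColumnError("x_max must exceed x_min")
    if not (x_min <= x <= x_max):
        raise ValueError(f"x={x} outside [{x_min}, {x_max}]")
    u = (x - x_min) / (x_max - x_min)
    return u if direction == POSITIVE else 1.0 - u


@dataclass
class IndexMatrix:
    """Cultivar x index matrix of scalar drought-stress index values."""

    values: pd.DataFrame
    directions: Mapping[str, str]

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2:
            raise ValueError("need at least 2 cultivars")
        if df.isna().any().any():
            raise ValueError("index matrix contains missing values")
        missing = [c for c in df.columns if c not in self.directions]
        if missing:
            raise ValueError(f"no direction declared for indices: {missing}")
        for col in df.columns:
            if df[col].max() <= df[col].min():
                raise DegenerateColumnError(
                    f"index column {col!r} is constant (max == min)"
                )


@dataclass
class MembershipTable:
    """Membership degrees per cultivar x index plus per-cultivar averages."""

    memberships: pd.DataFrame
    average: pd.Series = field(init=False)
    source: str = "computed"

    def __post_init__(self) -> None:
        m = self.memberships
        if m.empty:
            raise ValueError("empty membership table")
        if ((m < 0) | (m > 1)).any().any():
            raise ValueError("membership degrees must lie in [0, 1]")
        self.average = m.mean(axis=1)


@dataclass
class RankingResult:
    """Descending ranking of cultivars by unrounded average membership."""

    order: list[str]
    ranks: pd.Series
    ties: list[list[str]]


def build_membership_table(matrix: IndexMatrix) -> MembershipTable:
    """Column-wise min-max membership with each column's declared direction."""
    df = matrix.values
    out = {}
    for col in df.columns:
        lo, hi = float(df[col].min()), float(df[col].max())
        out[col] = [
            membership_degree(float(x), lo, hi, matrix.directions[col])
            for x in df[col]
        ]
    return MembershipTable(pd.DataFrame(out, index=df.index), source="computed")


def average_membership(
    table: MembershipTable, rounding: int = 2
) -> pd.DataFrame:
    """Raw (full-precision) and display-rounded composite scores."""
    raw = table.average
    rounded = raw.map(lambda v: round_half_up(v, rounding))
    return pd.DataFrame({"average_raw": raw, "average_rounded": rounded})


def rank_cultivars(scores: pd.Series) -> RankingResult:
    """Rank by descending raw score; exact ties keep input order.

    Tied groups are reported explicitly rather than silently resolved,
    because rounded composite scores commonly collide.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 cultivars to rank")
    vals = scores.to_numpy(dtype=float)
    # primary key: descending score; tie-break: input position
    perm = np.lexsort((np.arange(len(vals)), -vals))
    order_idx = scores.index[perm]
    ranks = pd.Series(
        np.arange(1, len(scores) + 1), index=order_idx, name="rank"
    ).reindex(scores.index)
    ties = [
        list(scores.index[scores == v])
        for v in scores.unique()
        if (scores == v).sum() > 1
    ]
    return RankingResult(order=list(order_idx), ranks=ranks, ties=ties)


@dataclass
class EvaluationReport:
    """Full comprehensive-evaluation output: memberships, scores, ranks."""

    membership: MembershipTable
    scores: pd.DataFrame
    ranking: RankingResult

    def to_frame(self) -> pd.DataFrame:
        """One table per cultivar: memberships, average and rank."""
        out = self.membership.memberships.copy()
        out["average"] = self.scores["average_rounded"]
        out["rank"] = self.ranking.ranks
        return out


def evaluate(
    data: IndexMatrix | MembershipTable | pd.DataFrame,
    directions: Mapping[str, str] | None = None,
    rounding: int = 2,
) -> EvaluationReport:
    """Comprehensive evaluation from raw index values or supplied memberships.

    A raw :class:`IndexMatrix` (or a DataFrame plus ``directions``) is first
    converted to membership degrees; a precomputed :class:`MembershipTable`
    is scored and ranked as-is.
    """
    if isinstance(data, pd.DataFrame):
        if directions is None:
            raise ValueError("directions required with a raw value matrix")
        data = IndexMatrix(values=data, directions=directions)
    if isinstance(data, IndexMatrix):
        table = build_membership_table(data)
    elif isinstance(data, MembershipTable):
        table = data
    else:
        raise TypeError(f"cannot evaluate {type(data).__name__}")
    scores = average_membership(table, rounding=rounding)
    ranking = rank_cultivars(scores["average_raw"])
    return EvaluationReport(membership=table, scores=scores, ranking=ranking)
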