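"""Cross-experiment comparison: matched change tables and summary statistics.

A comparison summary holds, per gene or event, the fold (or isoform-ratio)
change, P-value, and significance call of one two-sample comparison.  Pairs
of summaries — possibly from different platforms or organisms, joined
through an ID map — are matched item by item and classified into quadrants
(up/up, up/down, ... significant on one side only, or neither), mirroring a
four-way change scatter.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .stats import DOWN, UNCHANGED, UP

UPUP, UPDOWN, DOWNUP, DOWNDOWN = "UpUp", "UpDown", "DownUp", "DownDown"
XONLY, YONLY, NEITHER = "XOnly", "YOnly", "Neither"
QUADRANTS = [UPUP, UPDOWN, DOWNUP, DOWNDOWN, XONLY, YONLY, NEITHER]


@dataclasses.dataclass(frozen=True)
class ItemStats:
    fold: float
    p: float
    call: str


@dataclasses.dataclass
class ComparisonSummary:
    name: str
    kind: str  # "gene" or an event type
    items: dict[str, ItemStats]

    @classmethod
    def from_table(
        cls, name: str, table: pd.DataFrame, kind: str = "gene",
        fold_column: str | None = None,
    ) -> "ComparisonSummary":
        fold_col = fold_column or (
            "fold_change" if "fold_change" in table.columns else "ratio_change"
        )
        items = {
            str(idx): ItemStats(
                fold=float(row[fold_col]), p=float(row["p"]), call=row["call"]
            )
            for idx, row in table.iterrows()
        }
        return cls(name=name, kind=kind, items=items)


@dataclasses.dataclass(frozen=True)
class FourWayRow:
    id_x: str
    id_y: str
    x: ItemStats
    y: ItemStats
    quadrant: str


def fourway_classify(x: ItemStats, y: ItemStats) -> str:
    """Quadrant from the two sides' own significance calls and directions."""
    sig_x = x.call != UNCHANGED
    sig_y = y.call != UNCHANGED
    if sig_x and sig_y:
        return {
            (UP, UP): UPUP,
            (UP, DOWN): UPDOWN,
            (DOWN, UP): DOWNUP,
            (DOWN, DOWN): DOWNDOWN,
        }[(x.call, y.call)]
    if sig_x:
        return XONLY
    if sig_y:
        return YONLY
    return NEITHER


def match_items(
    summary_x: ComparisonSummary,
    summary_y: ComparisonSummary,
    idmap: list[tuple[str, str]] | None = None,
) -> list[FourWayRow]:
    """Join two comparison summaries item by item.

    Without an ID map, items join on exact id.  With a (many-to-many) map,
    one row is emitted per mapped pair present in both summaries.  Items
    absent from either side are omitted.
    """
    if idmap is None:
        pairs = [(i, i) for i in summary_x.items if i in summary_y.items]
    else:
        seen = set()
        pairs = []
        for ix, iy in idmap:
            if (ix, iy) in seen:
                continue
            seen.add((ix, iy))
            if ix in summary_x.items and iy in summary_y.items:
                pairs.append((ix, iy))
    rows = []
    for ix, iy in sorted(pairs):
        x = summary_x.items[ix]
        y = summary_y.items[iy]
        rows.append(FourWayRow(ix, iy, x, y, fourway_classify(x, y)))
    return rows


def fourway_table(rows: list[FourWayRow]) -> pd.DataFrame:
    """Tabular 4-way output: both sides' statistics repeated, plus quadrant."""
    return pd.DataFrame(
        [
            {
                "id_x": r.id_x, "id_y": r.id_y,
                "fold_x": r.x.fold, "p_x": r.x.p, "call_x": r.x.call,
                "fold_y": r.y.fold, "p_y": r.y.p, "call_y": r.y.call,
                "quadrant": r.quadrant,
            }
            for r in rows
        ],
        columns=["id_x", "id_y", "fold_x", "p_x", "call_x",
                 "fold_y", "p_y", "call_y", "quadrant"],
    )


def read_idmap(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return [(r[0], r[1]) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Curves and matrices
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EcdfCurve:
    values: np.ndarray
    fractions: np.ndarray


def ecdf_curve(values, log2: bool = False) -> EcdfCurve:
    """Empirical CDF of a value set, optionally on a log2 x-axis.

    Infinities sort to the curve extremes; at least one finite value is
    required.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0 or not np.any(np.isfinite(v)):
        raise ValueError("need at least one finite value")
    if log2:
        with np.errstate(divide="ignore"):
            v = np.log2(v)
    v = np.sort(v)
    frac = np.arange(1, v.size + 1) / v.size
    return EcdfCurve(values=v, fractions=frac)


def similarity_matrix(
    comparisons_x: list[ComparisonSummary],
    comparisons_y: list[ComparisonSummary],
    statistic: str = "fold_corr",
    idmap: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise similarity of change profiles from two comparison lists.

    ``fold_corr``: Pearson correlation of log2 fold changes over items
    finite in both comparisons.  ``signed_overlap``: among items significant
    in both, concordant minus discordant direction counts.  Cells without
    shared informative items are missing.
    """
    if statistic not in ("fold_corr", "signed_overlap"):
        raise ValueError(f"unknown statistic {statistic!r}")
    out = pd.DataFrame(
        np.nan,
        index=[c.name for c in comparisons_y],
        columns=[c.name for c in comparisons_x],
    )
    for cx in comparisons_x:
        for cy in comparisons_y:
            rows = match_items(cx, cy, idmap=idmap)
            if statistic == "fold_corr":
                lx, ly = [], []
                for r in rows:
                    with np.errstate(divide="ignore"):
                        fx = math.log2(r.x.fold) if r.x.fold > 0 else -math.inf
                        fy = math.log2(r.y.fold) if r.y.fold > 0 else -math.inf
                    if math.isfinite(fx) and math.isfinite(fy):
                        lx.append(fx)
                        ly.append(fy)
                if len(lx) >= 2 and np.std(lx) > 0 and np.std(ly) > 0:
                    out.loc[cy.name, cx.name] = float(
                        np.corrcoef(lx, ly)[0, 1]
                    )
            else:
                concordant = discordant = 0
                seen = False
                for r in rows:
                    if r.quadrant in (UPUP, DOWNDOWN):
                        concordant += 1
                        seen = True
                    elif r.quadrant in (UPDOWN, DOWNUP):
                        discordant += 1
                        seen = True
                if seen:
                    out.loc[cy.name, cx.name] = concordant - discordant
    return out


def set_change_matrix(
    gene_set: list[str], comparisons: list[ComparisonSummary]
) -> pd.DataFrame:
    """Gene-by-comparison fold-change matrix for a requested gene set.

    Row order follows the request; genes absent from a comparison get NaN.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    data = {}
    for c in comparisons:
        data[c.name] = [
            c.items[g].fold if g in c.items else np.nan for g in gene_set
        ]
    return pd.DataFrame(data, index=gene_set,
                        columns=[c.name for c in comparisons])
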