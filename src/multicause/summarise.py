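"""Aggregation of per-death weights into tables, rankings and comparisons.

The contribution of cause c to all deaths under a weighting scheme is the
sum over deaths i of the per-death weights w_ci; because each death's
weights sum to one, the contributions sum to the number of deaths, and are
reported as percentages of it.  Tables can be computed overall or within
strata (sex, age group).  Rankings order causes by decreasing percentage,
and Bland–Altman analysis quantifies agreement between the percentages of
two schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .certificates import ResolvedRecord
from .weighting import Scheme, WeightVector

__all__ = [
    "ContributionTable",
    "RankTable",
    "BlandAltman",
    "DEFAULT_P_GRID",
    "aggregate",
    "sweep_p",
    "rank",
    "bland_altman",
    "plot_bland_altman",
]

logger = logging.getLogger(__name__)

#: Default grid for the arbitrary-weight sensitivity sweep, from UCoD-only
#: (p = 1) down to CCoDs-only (p = 0).
DEFAULT_P_GRID: tuple[float, ...] = (1.0, 0.9, 0.7, 0.5, 0.3, 0.1, 0.0)

#: Limits-of-agreement multiplier (the conventional 95% band).
LOA_MULTIPLIER = 1.96


@dataclass
class ContributionTable:
    """Weighted death counts and percentage shares per category.

    ``table`` is indexed by category (every category appears, zero rows
    included) with columns ``weighted_count`` and ``percent``.
    """

    scheme: Scheme | None
    stratum: dict[str, str]
    table: pd.DataFrame
    total_deaths: int

    def percent(self, category: str) -> float:
        return float(self.table.at[category, "percent"])

    def weighted_count(self, category: str) -> float:
        return float(self.table.at[category, "weighted_count"])

    @property
    def categories(self) -> list[str]:
        return list(self.table.index)

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        """Report view with percentages rounded (internal values unrounded)."""
        out = self.table.copy()
        out["percent"] = out["percent"].round(ndigits)
        return out


@dataclass
class RankTable:
    """Per-category ranks under several schemes within one stratum.

    ``table`` is indexed by category, one column per scheme label; entries
    are integer ranks (1 = largest percentage) where the category falls in
    that scheme's top k, and <NA> otherwise.  Only categories in at least
    one scheme's top k appear, in best-rank order.
    """

    stratum: dict[str, str]
    table: pd.DataFrame


@dataclass
class BlandAltman:
    """Agreement between the percentage shares of two schemes.

    Per category: ``diff`` = a − b and ``mean`` = (a + b) / 2, in
    percentage points.  ``bias`` is the mean difference; the limits of
    agreement are bias ± 1.96 × SD(diff); ``flagged`` lists categories
    whose difference lies outside the limits, i.e. disagreements beyond
    what the overall scatter would suggest.
    """

    pairs: pd.DataFrame
    bias: float
    loa_low: float
    loa_high: float
    flagged: list[str]
    labels: tuple[str, str] = ("a", "b")


def _stratum_groups(
    records: Sequence[ResolvedRecord], axes: Sequence[str]
) -> dict[tuple[str, ...], list[int]]:
    groups: dict[tuple[str, ...], list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.stratum_key(axes), []).append(i)
    return groups


def aggregate(
    records: Sequence[ResolvedRecord],
    weights: Sequence[WeightVector],
    categories: Sequence[str],
    strata_axes: Sequence[str] = (),
    scheme: Scheme | None = None,
) -> list[ContributionTable]:
    """Sum per-death weights into contribution tables.

    With empty ``strata_axes`` a single overall table is returned;
    otherwise one table per observed combination of the stratum labels, in
    order of first appearance.  Weights must be paired 1:1 with records
    (matching ids).  Strata with no deaths are simply absent; an axis value
    missing on a record groups under the empty label with a warning.
    """
    records = list(records)
    weights = list(weights)
    if len(records) != len(weights):
        raise ValueError(
            f"{len(records)} records but {len(weights)} weight vectors"
        )
    for r, w in zip(records, weights):
        if r.id != w.record_id:
            raise ValueError(
                f"record/weight id mismatch: {r.id!r} vs {w.record_id!r}"
            )
    categories = list(categories)
    cat_index = {c: i for i, c in enumerate(categories)}
    tables: list[ContributionTable] = []
    for key, idxs in _stratum_groups(records, strata_axes).items():
        if "" in key:
            logger.warning(
                "stratum %s has records missing a stratum label", dict(zip(strata_axes, key))
            )
        counts = np.zeros(len(categories))
        for i in idxs:
            for c, v in weights[i].w.items():
                counts[cat_index[c]] += v
        total = len(idxs)
        df = pd.DataFrame(
            {"weighted_count": counts, "percent": 100.0 * counts / total},
            index=pd.Index(categories, name="category"),
        )
        tables.append(
            ContributionTable(
                scheme=scheme,
                stratum=dict(zip(strata_axes, key)),
                table=df,
                total_deaths=total,
            )
        )
    return tables


def sweep_p(
    records: Sequence[ResolvedRecord],
    categories: Sequence[str],
    p_values: Sequence[float] = DEFAULT_P_GRID,
) -> list[ContributionTable]:
    """Overall contribution tables under arbitrary weights, one per p.

    The default grid runs from p = 1 (UCoD-only) to p = 0 (CCoDs only),
    showing how each cause's share responds to moving mass from underlying
    to contributing causes.
    """
    from .weighting import compute_weights

    out: list[ContributionTable] = []
    for p in p_values:
        scheme = Scheme("arbitrary", float(p))
        w = compute_weights(records, scheme)
        out.extend(aggregate(records, w, categories, scheme=scheme))
    return out


def rank(tables: Sequence[ContributionTable], top_k: int = 10) -> RankTable:
    """Leading-cause ranks across schemes for one stratum.

    Categories are ordered by decreasing percentage within each scheme;
    ties break by position in the table's category list (stable and
    deterministic).  Only ranks up to ``top_k`` are reported; categories in
    no scheme's top k are omitted.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to rank")
    stratum = tables[0].stratum
    cats = tables[0].categories
    for t in tables[1:]:
        if t.stratum != stratum or t.categories != cats:
            raise ValueError("rank() needs tables sharing a stratum and category list")
    if not any(t.total_deaths for t in tables):
        raise ValueError("cannot rank an empty table")
    cols: dict[str, pd.Series] = {}
    for j, t in enumerate(tables):
        label = t.scheme.label if t.scheme is not None else f"scheme_{j + 1}"
        order = sorted(range(len(cats)), key=lambda i: (-t.table["percent"].iloc[i], i))
        ranks = pd.Series(pd.NA, index=cats, dtype="Int64", name=label)
        for r, i in enumerate(order[:top_k], start=1):
            ranks.iloc[i] = r
        cols[label] = ranks
    df = pd.DataFrame(cols)
    df = df[df.notna().any(axis=1)]
    df = df.loc[df.min(axis=1).sort_values(kind="stable").index]
    df.index.name = "category"
    return RankTable(stratum=stratum, table=df)


def bland_altman(a: ContributionTable, b: ContributionTable) -> BlandAltman:
    """Bland–Altman agreement between two schemes' percentage shares.

    Differences are a − b per category; the limits of agreement are
    bias ± 1.96 × SD of the differences (sample SD).  Categories outside
    the limits are flagged as disagreeing more than the overall scatter.
    """
    if a.stratum != b.stratum:
        raise ValueError("Bland-Altman requires tables from the same stratum")
    if a.categories != b.categories:
        raise ValueError("Bland-Altman requires identical category lists")
    pa = a.table["percent"]
    pb = b.table["percent"]
    diffs = pa - pb
    means = (pa + pb) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    half = LOA_MULTIPLIER * sd
    flagged = [c for c in a.categories if abs(diffs[c] - bias) > half]
    pairs = pd.DataFrame({"mean": means, "diff": diffs})
    pairs.index.name = "category"
    return BlandAltman(
        pairs=pairs,
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        flagged=flagged,
        labels=(
            a.scheme.label if a.scheme is not None else "a",
            b.scheme.label if b.scheme is not None else "b",
        ),
    )


def plot_bland_altman(ba: BlandAltman, path: str, title: str | None = None) -> None:
    """Render a Bland–Altman plot to ``path`` (format from the extension).

    Presentation only: the shaded band is the limits of agreement already
    stored on the :class:`BlandAltman`, flagged categories are labelled.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.axhspan(ba.loa_low, ba.loa_high, color="0.9", zorder=0)
    ax.axhline(ba.bias, color="0.4", lw=1)
    ax.axhline(ba.loa_low, color="0.4", lw=1, ls="--")
    ax.axhline(ba.loa_high, color="0.4", lw=1, ls="--")
    ax.scatter(ba.pairs["mean"], ba.pairs["diff"], s=18, color="C0", zorder=3)
    for cat in ba.flagged:
        ax.annotate(
            cat,
            (ba.pairs.at[cat, "mean"], ba.pairs.at[cat, "diff"]),
            textcoords="offset points",
            xytext=(4, 4),
            fontsize=8,
        )
    ax.set_xlabel(f"mean of {ba.labels[0]} and {ba.labels[1]} (%)")
    ax.set_ylabel(f"{ba.labels[0]} − {ba.labels[1]} (percentage points)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
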