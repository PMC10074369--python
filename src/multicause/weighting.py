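"""Per-death cause weights: data-driven, arbitrary-p, and equal schemes.

Conventional mortality statistics count each death once, under its single
underlying cause (UCoD).  Multiple-cause weighting instead splits each
death's unit mass across the causes mentioned on its certificate.  Three
schemes are implemented, all normalised so the weights of one death sum to
one (hence total weighted counts equal total deaths):

* **data-driven** — the share given to a contributing cause (CCoD) c on a
  death with UCoD u and n contributing causes is x_uc / n, where
  x_uc = N_{c|u} / N_u is the fraction of all deaths with UCoD u that
  mention c; the remainder 1 - Σ x_uc / n stays with the UCoD.  Frequent
  companions of a UCoD draw more mass than rare ones, with no tuning
  parameter.
* **arbitrary-p** — the UCoD keeps a fixed weight p in [0, 1] and the
  CCoDs share 1 - p equally; p = 1 recovers UCoD-only statistics.
* **equal** — UCoD and CCoDs each get 1 / (n + 1).

The data-driven scheme is a two-pass algorithm: pass one over all records
estimates the x-matrix, pass two assigns weights per record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .certificates import ResolvedRecord

__all__ = [
    "XMatrix",
    "WeightVector",
    "Scheme",
    "compute_x_matrix",
    "data_driven_weights",
    "arbitrary_weights",
    "equal_weights",
    "compute_weights",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class Scheme:
    """A weighting scheme: ``data_driven``, ``arbitrary`` (with p) or ``equal``.

    ``arbitrary`` with ``p=1`` is UCoD-only counting, the convention behind
    current national statistics.
    """

    kind: str
    p: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("data_driven", "arbitrary", "equal"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "arbitrary":
            if self.p is None:
                raise ValueError("arbitrary scheme requires p")
            if not 0.0 <= self.p <= 1.0:
                raise ValueError(f"p must be in [0, 1], got {self.p}")
        elif self.p is not None:
            raise ValueError(f"scheme {self.kind!r} takes no p")

    @property
    def label(self) -> str:
        if self.kind == "arbitrary":
            return "ucod_only" if self.p == 1 else f"arbitrary_p={self.p:g}"
        return self.kind

    @classmethod
    def ucod_only(cls) -> "Scheme":
        return cls("arbitrary", 1.0)


@dataclass
class XMatrix:
    """Conditional CCoD-mention fractions x_uc with the counts behind them.

    ``x.loc[u, c]`` is the fraction of deaths with UCoD category ``u`` that
    mention category ``c`` as a CCoD, zero on the diagonal.  Rows exist only
    for categories observed as a UCoD (``n_u > 0``); columns cover all
    categories.  ``n_u`` counts deaths per UCoD category over all
    categories, ``n_cu`` the per-pair mention counts (each death counted at
    most once per pair).
    """

    categories: list[str]
    n_u: pd.Series
    n_cu: pd.DataFrame
    x: pd.DataFrame
    _x_rows: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._x_rows:
            self._x_rows = {
                u: {c: v for c, v in row.items() if v} for u, row in self.x.iterrows()
            }

    def x_value(self, u: str, c: str) -> float:
        """x_uc; zero for never-mentioned pairs, KeyError for unseen UCoD u."""
        return self._x_rows[u].get(c, 0.0)

    def has_ucod(self, u: str) -> bool:
        return u in self._x_rows

    # -- audit I/O ----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write x as CSV (rows UCoD, columns CCoD, 15 significant digits)."""
        self.x.to_csv(path, index_label="ucod", float_format="%.15g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "XMatrix":
        """Reload an exported x-matrix (counts are not round-tripped)."""
        x = pd.read_csv(path, index_col="ucod", comment="#")
        cats = list(x.columns)
        empty = pd.DataFrame(0, index=x.index, columns=x.columns)
        return cls(cats, pd.Series(0, index=cats), empty, x)


@dataclass(frozen=True)
class WeightVector:
    """One death's weights: category -> share of the death, summing to one."""

    record_id: str
    w: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"record {self.record_id!r}: weights sum to {total!r}, not 1"
            )
        if any(v < -_WEIGHT_TOL for v in self.w.values()):
            raise ValueError(f"record {self.record_id!r}: negative weight")


def compute_x_matrix(
    records: Sequence[ResolvedRecord], categories: Sequence[str] | None = None
) -> XMatrix:
    """Pass one of the data-driven method: estimate x_uc from all records.

    For each pair (u, c), ``n_cu`` counts deaths with UCoD category u
    mentioning c as a CCoD (at most once per death), ``n_u`` counts deaths
    with UCoD u, and ``x = n_cu / n_u`` with a structural zero on the
    diagonal.  ``categories`` fixes the category order (e.g. the mapping's
    report order); by default the observed categories are used in sorted
    order.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot estimate an x-matrix from zero records")
    if categories is None:
        observed: set[str] = set()
        for r in records:
            observed.add(r.ucod_cat)
            observed.update(r.ccod_cats)
        categories = sorted(observed)
    else:
        categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    n_u = np.zeros(k, dtype=np.int64)
    n_cu = np.zeros((k, k), dtype=np.int64)
    for r in records:
        try:
            u = index[r.ucod_cat]
        except KeyError:
            raise ValueError(
                f"record {r.id!r}: category {r.ucod_cat!r} not in category list"
            ) from None
        n_u[u] += 1
        for c in r.ccod_cats:
            n_cu[u, index[c]] += 1
    # diagonal of n_cu is structurally zero: a ResolvedRecord never lists
    # its UCoD category among its CCoDs
    ucod_mask = n_u > 0
    x = n_cu[ucod_mask] / n_u[ucod_mask, None]
    row_cats = [c for c, m in zip(categories, ucod_mask) if m]
    x_df = pd.DataFrame(x, index=row_cats, columns=categories)
    return XMatrix(
        categories=list(categories),
        n_u=pd.Series(n_u, index=categories, name="n_u"),
        n_cu=pd.DataFrame(n_cu, index=categories, columns=categories),
        x=x_df,
    )


def data_driven_weights(record: ResolvedRecord, xm: XMatrix) -> WeightVector:
    """Pass two of the data-driven method: weights for one death.

    Each CCoD c receives x_uc / n (n = number of CCoDs on the record); the
    UCoD keeps the remainder.  Because every x_uc lies in [0, 1], the UCoD
    weight is never negative.  A death with no CCoDs keeps full weight on
    its UCoD.
    """
    u = record.ucod_cat
    if not xm.has_ucod(u):
        raise KeyError(
            f"record {record.id!r}: UCoD category {u!r} has no deaths in the x-matrix"
        )
    n = record.n_ccod
    if n == 0:
        return WeightVector(record.id, {u: 1.0})
    w = {c: xm.x_value(u, c) / n for c in record.ccod_cats}
    w[u] = 1.0 - sum(w.values())
    if w[u] < 0.0:  # guard against accumulated rounding at exact zero
        if w[u] < -_WEIGHT_TOL:
            raise AssertionError(
                f"record {record.id!r}: negative UCoD weight {w[u]!r}"
            )
        w[u] = 0.0
    return WeightVector(record.id, w)


def arbitrary_weights(record: ResolvedRecord, p: float) -> WeightVector:
    """Fixed-split weights: UCoD keeps p, CCoDs share 1 - p equally.

    With no CCoDs the UCoD keeps the full unit weight regardless of p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n = record.n_ccod
    if n == 0:
        return WeightVector(record.id, {record.ucod_cat: 1.0})
    share = (1.0 - p) / n
    w = {c: share for c in record.ccod_cats}
    w[record.ucod_cat] = p
    return WeightVector(record.id, w)


def equal_weights(record: ResolvedRecord) -> WeightVector:
    """Every listed cause, underlying or contributing, gets 1 / (n + 1)."""
    causes = {record.ucod_cat, *record.ccod_cats}
    share = 1.0 / len(causes)
    return WeightVector(record.id, {c: share for c in causes})


def compute_weights(
    records: Iterable[ResolvedRecord],
    scheme: Scheme,
    xm: XMatrix | None = None,
) -> list[WeightVector]:
    """Weights for many records under one scheme.

    The data-driven scheme needs the x-matrix from
    :func:`compute_x_matrix`; pass the one estimated on the full data (or
    on a stratum, for within-stratum estimation).
    """
    records = list(records)
    if scheme.kind == "data_driven":
        if xm is None:
            xm = compute_x_matrix(records)
        return [data_driven_weights(r, xm) for r in records]
    if scheme.kind == "arbitrary":
        return [arbitrary_weights(r, scheme.p) for r in records]
    return [equal_weights(r) for r in records]
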