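"""Independent exact-rational brute force for cross-checking the pipeline.

Works from raw (UCoD, CCoD-list) tuples with :class:`fractions.Fraction`
throughout, re-deriving the x-matrix from scratch; deliberately shares no
code with the package implementation.
"""

from collections import Counter, defaultdict
from fractions import Fraction


def resolve(rows):
    """Deduplicate CCoDs and drop the UCoD from each CCoD list."""
    return [(u, sorted(set(cc) - {u})) for u, cc in rows]


def x_fraction(rows, u, c):
    """x_uc recomputed from scratch as an exact rational."""
    resolved = resolve(rows)
    n_u = sum(1 for uu, _ in resolved if uu == u)
    n_cu = sum(1 for uu, cc in resolved if uu == u and c in cc)
    if u == c:
        return Fraction(0)
    return Fraction(n_cu, n_u)


def contributions(rows, scheme, p=None):
    """Total weighted counts per category, as exact rationals.

    ``scheme`` is one of ``"data_driven"``, ``"arbitrary"`` (with ``p``),
    ``"equal"``.
    """
    resolved = resolve(rows)
    n_u = Counter(u for u, _ in resolved)
    n_cu = Counter((u, c) for u, cc in resolved for c in cc)
    totals = defaultdict(Fraction)
    for u, cc in resolved:
        n = len(cc)
        if n == 0:
            weights = {u: Fraction(1)}
        elif scheme == "data_driven":
            weights = {c: Fraction(n_cu[(u, c)], n_u[u]) / n for c in cc}
            weights[u] = 1 - sum(weights.values())
        elif scheme == "arbitrary":
            pf = Fraction(p)
            weights = {c: (1 - pf) / n for c in cc}
            weights[u] = pf
        elif scheme == "equal":
            weights = {c: Fraction(1, n + 1) for c in [u, *cc]}
        else:
            raise ValueError(scheme)
        assert sum(weights.values()) == 1
        for c, v in weights.items():
            totals[c] += v
    return dict(totals)


def percents(rows, scheme, p=None):
    """Contribution percentages per category, as exact rationals."""
    totals = contributions(rows, scheme, p)
    n = len(rows)
    return {c: 100 * v / n for c, v in totals.items()}
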