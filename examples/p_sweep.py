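"""Sensitivity of cause shares to the arbitrary weight p.

Under the arbitrary scheme the underlying cause keeps weight p and the
contributing causes share 1 - p equally.  Sweeping p from 1 (UCoD-only,
today's national-statistics convention) to 0 (contributing causes only)
shows how strongly each cause's share depends on that subjective choice.
On the worked example, cause D (rarely a contributing cause) falls from
20% to 10% as p drops, while C (often a contributing cause) more than
doubles — the data-driven column sits where co-occurrence patterns put it,
with no p to choose.
"""

from multicause import (
    Scheme,
    aggregate,
    compute_weights,
    compute_x_matrix,
    fixture_mapping,
    resolve_records,
    sweep_p,
    table1_fixture,
)

mapping = fixture_mapping()
records = resolve_records(table1_fixture(), mapping)
cats = mapping.categories

tables = sweep_p(records, cats)  # default grid: 1, 0.9, 0.7, 0.5, 0.3, 0.1, 0

xm = compute_x_matrix(records, cats)
dd = Scheme("data_driven")
(dd_table,) = aggregate(records, compute_weights(records, dd, xm), cats, scheme=dd)

header = f"{'cause':>6} {'data-driven':>12} " + " ".join(
    f"p={t.scheme.p:g}".rjust(7) for t in tables
)
print(header)
for c in cats:
    row = " ".join(f"{t.percent(c):7.2f}" for t in tables)
    print(f"{c:>6} {dd_table.percent(c):12.2f} {row}")
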