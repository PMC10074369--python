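# Methods

## Model and procedure

The unit of analysis is the death, not the cause mention: every death
carries total weight one, however many causes its certificate lists, so
weighted counts are comparable with conventional UCoD-only tabulations and
robust to certification styles that differ in how many contributing causes
they record.

The data-driven scheme is a two-pass procedure. Pass one uses **all** the
records to estimate, for every ordered pair of cause categories `(u, c)`,

- `N_u` — deaths with underlying cause `u`;
- `N_{c|u}` — deaths with underlying cause `u` that mention `c` as a
  contributing cause (a death counts at most once per pair, however often
  `c` appears on it);
- `x_uc = N_{c|u} / N_u`, with a structural zero on the diagonal.

Pass two revisits each death `i` (UCoD `u`, `n_i` distinct contributing
categories) and assigns `w_ci = x_uc / n_i` to each contributing cause and
the remainder `1 − Σ x_uc / n_i` to the UCoD. Since `x_uc ≤ 1` and there
are `n_i` terms each at most `1/n_i`, the UCoD weight is never negative;
it reaches zero exactly when every contributing cause co-occurs with `u`
on every death (as happens in the worked example's record 8). A death
with no contributing causes keeps weight one on its UCoD under every
scheme.

The comparators are the fixed-split scheme (`p` to the UCoD, `1 − p`
shared equally among contributing causes) and equal weights
(`1/(n_i + 1)` each, identical to the fixed split at `p = 1/(n_i + 1)`).
`p = 1` reproduces UCoD-only statistics exactly; this identity is tested.

### Assumptions

- The designated UCoD is taken as given (it is produced upstream by ICD-10
  selection rules); no re-derivation is attempted.
- Categories are mutually exclusive and exhaustive; all counting happens
  after mapping codes to categories, so a category mentioned twice on one
  certificate counts once, and a category that is both UCoD and CCoD
  counts only as the UCoD.
- `x_uc` is a pooled estimate over the full input by default. Stratified
  reporting (sex × age) reuses the pooled `x` unless within-stratum
  estimation is requested (`--stratified-x`); pooling follows the method's
  "use all the data" rule, while the flag covers the alternative reading
  for stratified tables.

## Certificate resolution

Contributing causes are the Part I codes strictly *after* the UCoD in
reading order — positions to its right on the same line, then all codes on
later lines — plus every Part II code. Codes above the UCoD (earlier
lines, or earlier positions on its own line) are consequences of the UCoD
and are ignored. Codes left of the UCoD on the same line are treated as
"above": the extraction rule is phrased in terms of what lies to the right
of or below the UCoD, and only those codes are plausible pre-mortem
comorbidities. Record-axis input has lost positional information, so all
non-first causes are candidates there. A `part2_only` switch restricts
candidates to Part II, replicating the narrower convention of earlier
fixed-weight analyses; by default all three schemes consume the same
resolved records so that scheme comparisons reflect weighting, not
extraction.

## Category mapping

Mappings are ordered lists of `(pattern, category)` rows: exact codes
(`G30`), code ranges (`C18-C21`), decimal ranges (`Y87.1-Y87.9`) and
chapter letters (`V`). Patterns are compiled to disjoint integer intervals
over the code space; any overlap is a construction-time error, which
enforces mutual exclusivity mechanically. Lookup tries the full code, then
its three-character root. Unmappable codes are a hard error by default —
silently dropping them would bias `x_uc` — with a lenient mode that routes
them to an `Unclassified` category barred from UCoD roles (records whose
UCoD itself is unclassifiable are excluded with a logged count).

The shipped 40-category default condenses ICD-10 for mortality at ages 60
and over: common cancers singular; dementias pooled across chapters
(F00–F03 with G30); suicide kept separate (X60–X84, Y87.0); external-cause
mechanism codes (V, W20–W99, X00–X59, X85–X99, Y00–Y86, Y87.1–Y87.9,
Y88–Y99) pooled with injury-nature codes (S, T); accidental falls
(W00–W19) singular; a terminal category for U and Z codes. Where the
published groupings do not pin down a boundary, standard chapter blocks
fill the gaps (e.g. kidney disease N00–N29 vs other genitourinary
N30–N99). It is explicitly a best-effort default, and any analysis that
matters should load its own list via `CategoryMapping.from_file`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p` (arbitrary scheme) | 0.5 in the CLI | fixed UCoD share; sweep grid 1, 0.9, 0.7, 0.5, 0.3, 0.1, 0 |
| `age_breaks` | (60, 75, 85) years | groups 60–74, 75–84, 85+; younger deaths are excluded with a logged count |
| `top_k` | 10 | ranking cutoff for leading-cause tables |
| limits-of-agreement multiplier | 1.96 | the Bland–Altman 95% convention |
| `max_ccods` (generator) | effectively unbounded | truncation cap on mentions per certificate |

Reported percentages are rounded to two decimals; internal values are
never rounded. Ranking ties break deterministically by position in the
category list.

## Synthetic data

The generator draws each death's UCoD from a categorical distribution and
then mentions every other category independently with probability
`m[u][c]` (zero diagonal), emitting the UCoD as a one-line Part I and the
mentions as Part II. Conditional independence given the UCoD is the
minimal structure under which `x_uc` is identifiable and equals `m[u][c]`
in expectation, which makes parameter recovery an exact binomial question;
it deliberately omits features of real certificates — causal Part I
chains, correlated comorbidity clusters, coding error, secular trends — so
passing recovery tests demonstrates correctness of the estimator, not
fidelity of the generator to real mortality data. Truncation by
`max_ccods` takes a uniform random subset and should be left slack
whenever recovery is being measured (binding truncation biases marginal
mention rates downward). One seeded NumPy `default_rng` stream drives a
`generate` call, so populations are bit-reproducible from the config.

Validation sizes were chosen to make sampling noise negligible at test
speed: 10,000 records for equivalence and conservation checks, 50,000 ×
20 seeds for x-matrix recovery (each cell then has standard error below
0.004, and ≥ 99% of cells are required within three binomial SEs), and
100 populations of ≤ 20 records for exact-rational cross-checks.

## Numerical choices

- Weights and aggregates accumulate in double precision; the independent
  test oracle recomputes everything in exact rational arithmetic
  (`fractions.Fraction`) from the raw records, and totals must agree to
  1e-9.
- `x_uc` for a pair never observed together is exactly 0 (no smoothing:
  the method defines none, and the affected weight mass simply stays with
  the UCoD).
- A tiny negative UCoD weight from floating-point cancellation (the exact
  value being zero) is clamped to zero; anything below −1e-12 raises.
- Bland–Altman uses the sample standard deviation (ddof = 1); with a
  single category, or two identical tables, the limits collapse to the
  bias and nothing is flagged.
- Empty strata are omitted rather than raised; records missing a stratum
  label group under an empty label with a warning.

## Known limitations

- No uncertainty quantification for `x_uc` or the resulting percentages.
- No age-standardised rates, person-years denominators or trend analysis;
  outputs are percentage shares of deaths.
- The shipped category list is a reconstruction suited to older
  populations in settings where non-communicable disease dominates; other
  settings need their own list.
- ICD-10 only; no ICD-9/ICD-11 support, and no implementation of UCoD
  selection rules.
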