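# Methods

## Scope and model

`fhrecall` re-implements, as tested library code, the analysis chain of
a recall-by-genotype (RbG) follow-up of familial hypercholesterolemia
(FH) variant carriers in a national biobank with EHR and prescription
registry linkage. The chain is: carrier screening against an
LDLR/APOB/PCSK9 variant panel → group assignment (recalled vs
never-recalled controls) → ICD-10 phenotype flags → refill-based
adherence episode reconstruction and classification → SLCO1B1
statin-myopathy risk translation → Likert survey scoring → exact
two-tailed group comparisons. Because the underlying registries cannot
be redistributed, a synthetic registry generator emulates the full
linkage, and every stage is exercised on it.

## Exact test

Group comparisons use Fisher's exact test on 2×2 tables (group ×
phenotype). The two-tailed p-value is the *minimum-likelihood*
definition: with margins fixed, sum the hypergeometric point
probabilities P(X = x) of every table whose probability does not
exceed that of the observed table,

    P(X = a | margins) = C(a+b, a) · C(c+d, c) / C(n, a+c).

This is the definition used by Langsrud's calculator (after Agresti);
the "doubling" alternative gives different p-values and is not
offered. Numerics: binomial coefficients are evaluated as log-gamma
differences and exponentiated per term, since n ≈ 325 overflows naive
factorials; tied tails are compared with relative tolerance 1e-7
(`TIE_RTOL`) because equal probabilities on opposite tails differ in
their last floating bits. The p-value is clamped to (0, 1]; the
observed table always contributes its own probability, so 0 is
impossible. Tests cross-check the implementation against two
independent routes: an exact rational enumeration (integer binomial
coefficients with `fractions.Fraction`) and `scipy.stats.fisher_exact`.

Percentages in comparison tables are reported to 1 decimal place with
half-up rounding, always together with their denominator — gene-level
percentages in a cohort containing a dual-gene carrier are otherwise
ambiguous, and the ambiguity should be impossible to reproduce
silently.

## Adherence episodes

One purchase covers `n_packages × pills_per_package` days at one
tablet per day (no DDD scaling — the dose assumption is fixed). A
purchase made before the previous supply runs out starts its coverage
at the running supply end (stockpiling carry-forward). The same-day
multiple-purchase case is the extreme of this rule; we generalize it to
any overlapping purchase, which gives the supply-conservation
invariant: covered days always equal dispensed days, for any purchase
pattern (property-tested on randomized histories).

Intervals are half-open `[start, end)` at day resolution; the gap
between consecutive intervals is `next.start − prev.end` in days.
Intervals with gaps strictly greater than the threshold split into
separate treatment episodes; a gap of exactly the threshold merges.
Episode splitting is monotone in the threshold.

Classification thresholds (all configurable, defaults in days):

| parameter | default | meaning |
|---|---|---|
| `gap_threshold_days` | 183 | six-month gap that ends an episode |
| `prior_consistent_days` | 730 | "≥2 years" of prior consistent use |
| `shortly_after_days` | 365 | "initiation shortly after" the visit |
| `ongoing_slack_days` | 183 | episode end this close to follow-up end counts as ongoing |

Only the six-month gap is quantified by the source rules; the other
three are this package's explicit operationalizations. The three
classes are: CONSISTENT_POST_VISIT (an episode covers the visit date or
starts within `shortly_after_days` after it *and* that episode runs to
within `ongoing_slack_days` of follow-up end), else
PRIOR_CONSISTENT_TERMINATED (some episode of ≥ `prior_consistent_days`
starts before the visit and no supply falls in the final
`ongoing_slack_days`), else POOR. CONSISTENT_POST_VISIT is checked
first: an ongoing user with an old long episode is adherent now.
Episodes are pooled across substances for classification
(treatment-level adherence) but kept per-substance for the Gantt
export, which colors by active substance. Per-participant visit dates
are accepted explicitly; the midpoint of the visit window is the
fallback when none are supplied.

## Phenotype flags

E78\* flags use prefix matching after normalizing dotted ("E78.0") and
undotted ("E780") registry dialects; E78.0 defaults to prefix matching
(so E78.00 counts) with a strict exact-code option. Flags are
ever-diagnosed over the whole EHR window — dates are ignored. The
diagnosis-burden count truncates codes to 3-character stems, counts
each stem once per person, and drops Z-chapter stems; the Z exclusion
applies only to the burden count, never to flags. LLT users are
participants with ≥1 purchase in ATC class C10\*.

## Pharmacogenomics

SLCO1B1 decreased-function allele count (0/1/2) maps to
NORMAL/HIGHER/MUCH_HIGHER myopathy risk. The input is the allele
count, not raw array calls: the canonical marker is c.521T>C
(rs4149056), but the translation pipeline's variant set is not part of
this package's contract, so only the three-category output is
reproduced. The warning applies to simvastatin, atorvastatin and
rosuvastatin; profiles flag users whose statin falls outside that set.
On-statin lipids are back-adjusted by TC/0.8 and LDL-C/0.7; the
adjustment is linear, order-preserving, and the identity off statin.

## Synthetic registry generator

The generator's defaults are the study conditions: 34 recalled / 291
controls; E78\* prevalence 0.941/0.670 (recalled/control), E78.0
0.824/0.460, LLT use 0.794/0.533; SLCO1B1 risk-allele frequency 0.16
under Hardy-Weinberg (expected heterozygote fraction 2pq ≈ 0.269,
homozygote q² ≈ 0.026); archetype weights 11:13:4; follow-up
2004-01-01..2022-03-31 with visits uniform in 2016-2018; survey
nonresponse 0.25 per recipient, independently.

Design points:

- **Nested outcome draw.** A single uniform draw per participant
  assigns E78.0 (first p_e780 slice) or a non-.0 E78 subcode (next
  p_e78 − p_e780 slice), so E78.0 carriers are a subset of E78\*
  carriers at exactly the configured marginals.
- **Background burden.** Unique-code burden is Poisson around the
  target mean (default 41), drawn without replacement from a fixed
  embedded list of ~200 plausible non-E78, non-Z ICD-10 stems, so the
  calibration needs no external terminology.
- **Archetype layouts.** POOR histories are sparse single-purchase
  episodes with inter-purchase gaps of 215-600 days (always above the
  183-day threshold) ending well before follow-up end;
  CONSISTENT_POST_VISIT histories start within ±300 days of the visit
  and refill with gaps of −30..120 days until follow-up end;
  PRIOR_CONSISTENT_TERMINATED histories run ≥800 days starting well
  before the visit and stop near it, leaving the final six months
  uncovered. About a tenth of multi-package purchases are split into
  same-day duplicate rows to exercise the carry-forward. Under the
  default windows these layouts round-trip through the classifier at
  100%; the acceptance property requires ≥95%.
- **Variants.** Each participant carries exactly one panel variant
  drawn from the printed per-group frequency table (a dual-carrier is
  representable via a flag, off by default). "novel" variants emit
  sequencing calls; the rest are genotyped/imputed with a
  BOTH-dominant 225:33:33 source mix.
- **Determinism.** Every table draws from a stream keyed on
  `(seed, table name)`, so identical configs give byte-identical
  tables regardless of call order.

What the generator does **not** emulate: response-propensity structure
in nonresponse, co-prescription of combination regimens (substance
switching is modelled, concurrent dual supply is not, so synthetic
combination-use fractions are near zero), mortality and censoring,
seasonal purchase patterns, dose titration, linkage errors, and any
correlation between adherence and diagnosis burden. Passing round-trip
and recovery tests therefore show the pipeline is internally coherent
under the configured marginals — not that it is calibrated to real
registry behaviour.

## Problem sizes and degenerate inputs

The test and acceptance runs use: 1,000 randomized purchase histories
for supply conservation; an exhaustive grid over cell values
{0,1,2,3,5,8,13,15} (table totals ≤ 60, 4,095 tables) for exact-test
oracle agreement; a 10,000-control cohort for parameter recovery (3
binomial-SE bands); and the 34/291 cohort for the archetype
round-trip. Degenerate inputs are defined, not special-cased:
probability 0/1 configs, empty call tables, single-participant
cohorts, zero-response survey items (reported missing, never 0), and
the `[[0,0],[0,1]]` contingency table (point probability 1).

## Known limitations

- Adherence is episode logic only; no proportion-of-days-covered or
  MPR summaries.
- Odds-ratio confidence intervals, mid-p variants and multiple-testing
  correction are out of scope (comparisons report unadjusted exact p).
- Zygosity of FH variants is not modelled (dominant carrier flags).
- The panel is user-supplied; the embedded variant table is a default
  frequency table for simulation, not a clinical panel definition.
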