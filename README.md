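# fhrecall

Recall-by-genotype (RbG) follow-up analytics for familial
hypercholesterolemia (FH), with a synthetic registry generator so the
whole pipeline runs without participant data.

## The problem

RbG studies identify biobank participants carrying actionable genotypes
— here FH variants in *LDLR*, *APOB* and *PCSK9* — recall them for
result disclosure, and later ask whether the disclosure changed
anything. Answering that requires linking several registries per
participant and comparing recalled carriers against never-recalled
controls with the same variants: ICD-10 diagnosis codes (E78\*,
disorders of lipoprotein metabolism; E78.0, pure hypercholesterolemia,
the clinical FH code), pharmacy purchases of lipid-lowering treatment
(LLT, ATC class C10\*), SLCO1B1 statin-myopathy pharmacogenetics, and a
feedback survey. This package implements each stage as library code
for analysts running genotype-first follow-ups on registry linkage
data.

## What it computes

- **Carrier screening** (`fhrecall.cohort`): match genotyped / imputed /
  sequenced calls against an FH variant panel, tier the evidence
  (BOTH > single source; sequencing confirms), assign groups, and
  summarize per gene and variant with explicit denominators.
- **EHR phenotypes** (`fhrecall.phenotypes`): E78\*/E78.0 flags (dotted
  and undotted dialects), diagnosis burden as unique 3-character codes
  per person excluding Z codes, and LLT-user flags from ATC codes.
- **Adherence** (`fhrecall.adherence`): days of supply = packages ×
  pills at one tablet/day; stockpiling carry-forward; treatment
  episodes split at gaps > 183 days; classification of each user as
  POOR, CONSISTENT_POST_VISIT, or PRIOR_CONSISTENT_TERMINATED relative
  to their feedback visit; per-substance Gantt export and
  drug-exposure fractions.
- **Pharmacogenomics** (`fhrecall.pgx`): SLCO1B1 decreased-function
  allele count → NORMAL / HIGHER / MUCH_HIGHER myopathy risk
  (applicable to simvastatin, atorvastatin, rosuvastatin);
  statin-adjusted lipids (TC/0.8, LDL-C/0.7); flat per-participant
  profiles.
- **Exact statistics** (`fhrecall.stats`): two-tailed Fisher's exact
  test by hypergeometric enumeration in log space, summing all
  same-margin tables whose point probability

      P(X = a | margins) = C(a+b, a) · C(c+d, c) / C(n, a+c)

  does not exceed the observed one (the minimum-likelihood / Agresti
  definition); comparison tables with counts, 1-d.p. percentages and
  their denominators.
- **Survey scoring** (`fhrecall.survey`): 1-5 Likert encoding for
  agreement and healthcare-rating scales, per-item means, categorical
  tabulation, response rate.
- **Synthetic registry** (`fhrecall.synthetic`): all six linkage tables
  with configurable group-wise prevalences, adherence archetypes
  (mixed 11:13:4 by default) laid out to round-trip through the
  classifier, and Hardy-Weinberg pharmacogene genotypes.

## Worked example

`analysis/` contains numbered drivers that run the full study on a
synthetic cohort (34 recalled / 291 controls, seed 2022) and write
tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/03_phenotype_comparison.py
```

prints, among other things:

```
group comparison (recalled vs control):
  phenotype  group1_n  group1_total  group1_pct  group2_n  group2_total  group2_pct  p_value
has_e78_any        33            34        97.1       199           291        68.4 0.000179
   has_e780        25            34        73.5       134           291        46.0 0.003264
is_llt_user        27            34        79.4       163           291        56.0 0.009577
```

Read: 33 of 34 synthetic recalled carriers (97.1%) have an E78\* code
versus 68.4% of controls, and the exact two-tailed p-value for that
2×2 table is 1.8e-4 — the synthetic cohort reproduces the configured
recalled-vs-control contrast in diagnosis and treatment rates.
`analysis/04_adherence.py` then classifies the LLT users
(CONSISTENT_POST_VISIT 108, POOR 66, PRIOR_CONSISTENT_TERMINATED 16 in
this draw) and reports that 100% of generated histories recover their
intended archetype.

The same pipeline runs from the shell on any directory of linkage
CSVs:

```sh
fhrecall simulate --out cohort/ --seed 7
fhrecall report --in-dir cohort/ --out bundle/
fhrecall adherence --prescriptions cohort/prescriptions.csv --out adh/
```

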