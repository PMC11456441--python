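# harmburden

Rare-variant consensus deleteriousness scoring and case-control
burden/association analysis, built for candidate-pathway studies of the
insulin-like growth factor (IGF) signaling pathway in autism spectrum
disorder — and reusable for any gene-panel rare-variant screen that
consumes annotated variant tables and per-sample genotypes.

## Who this is for

Statistical geneticists analysing whole-exome case-control cohorts at the
scale of a candidate pathway: a few hundred cases and controls, a panel of
18 pathway genes (two IGF ligands, two receptors, six IGF binding
proteins, and eight downstream PI3K/AKT and MAPK factors), annotated
variant calls from a standard annotation pipeline, and per-sample
genotypes in VCF.

## The model

**Consensus deleteriousness (HARM).** Twelve in-silico predictors (SIFT,
Polyphen2 HDIV/HVAR, LRT, MutationTaster, MutationAssessor, FATHMM,
PROVEAN, fathmm-MKL coding, MetaSVM, MetaLR, CADD) each classify a variant
as deleterious (D), probably deleterious (P) or tolerable (T) according to
the tool's own convention (CADD: PHRED score ≥ 15 is deleterious). With
per-variant tallies *nD*, *nP*, *nT*:

```
HARM = nD + 0.4·nP − nT
```

A variant is called deleterious when (1) *nD* > 0 **and** (2) HARM > 0
(the conjunction is the default; either criterion alone is a switch).
Missing predictions count toward none of the tallies.

**Rarity and QC.** A variant is rare when its allele frequency is below
0.01 in the study controls and in at least one of six public population
databases (1000g ALL/EAS, ESP6500, ExAC, gnomAD controls all/EAS);
variants must have a call rate strictly above 0.95 to enter any analysis.

**Burden and association.** Per-individual mutation burden (count of
qualifying rare-deleterious variants carried) is compared between cases
and controls with a one-tailed two-sample test selected adaptively —
Student's t (normal, equal variances), Welch's t (normal, unequal
variances) or Mann-Whitney U (non-normal) — with normality and variance
homogeneity assessed by Shapiro-Wilk and Levene at α = 0.05. Carrier
enrichment in cases is tested per variant and per gene (carrier-collapsing)
with the one-tailed Fisher exact test, i.e. the hypergeometric upper tail
P(X ≥ observed case carriers), and p-values receive both
Benjamini-Hochberg and Bonferroni correction within each analysis level.

**Screens and reports.** Case-exclusivity screening retains qualifying
variants with ≥ 1 case carrier and zero carriers in the configured
comparison groups; pathway-category summaries and gene-set
overlap/cross-reference operations round out the reporting layer.

A synthetic-cohort generator (`harmburden.simulate`) emulates the cohort
structure the analysis assumes — Hardy-Weinberg genotypes over a
log-uniform frequency spectrum, genotype missingness, noisy database
frequencies, per-tool predictions of configurable concordance — with
planted prevalence gaps and case-exclusive variants recorded in a truth
ledger for recovery testing.

## Worked example

Simulate a cohort of 263 cases and 294 controls over 60 pathway variants,
with a planted 0.10 case-vs-control gap in qualifying-carrier prevalence
and 3 planted case-exclusive variants (4 case carriers each), then run the
full pipeline:

```python
from harmburden import carrier_prevalence
from harmburden.simulate import SimulationConfig, simulate_cohort
from harmburden.pipeline import score_variants, burden_and_association, screen_exclusive

cfg = SimulationConfig(n_variants=60, n_exclusive_planted=3,
                       exclusive_carrier_count=4, prevalence_gap=0.10,
                       missing_rate=0.0, seed=11)
matrix, records, truth = simulate_cohort(cfg)

scored = score_variants(matrix, records)          # QC + HARM + rarity
prev, p = carrier_prevalence(matrix, scored.qualifying_ids)
burden, assoc = burden_and_association(scored, records)
report = screen_exclusive(scored, records)
```

which prints (exactly reproducible with this seed):

```
scored: 60  qualifying: 15
prevalence: {'case': 0.175, 'control': 0.068}  p = 7.51e-05
 case_mean  control_mean  chosen_test  p_one_tailed
  0.197719      0.071429 mann_whitney      0.000044
case-exclusive: 3  planted: 3
      variant_id   gene  n_case  n_control
chr1:1000100:A:G IGFBP4       4          0
chr1:1000520:A:G MAP2K1       4          0
chr1:1000590:A:G   AKT1       4          0
```

Reading the numbers: 15 of 60 variants are both rare and deleterious
under the HARM rule; 17.5% of cases versus 6.8% of controls carry at
least one of them (one-tailed Fisher p ≈ 7.5e-05 — the planted gap is
detected); the adaptive burden test picks Mann-Whitney (burden counts are
far from normal) and agrees; and the exclusivity screen recovers exactly
the three planted case-exclusive variants with their true carrier counts.

The same pipeline is scriptable from a shell:

```sh
harmburden simulate --out sim --seed 11 --n-variants 60
harmburden score   --out scored --vcf sim/genotypes.vcf \
    --annotations sim/annotations.tsv --samples sim/samples.tsv
harmburden assoc   --out assoc  --vcf sim/genotypes.vcf \
    --annotations sim/annotations.tsv --samples sim/samples.tsv
harmburden screen  --out screen --vcf sim/genotypes.vcf \
    --annotations sim/annotations.tsv --samples sim/samples.tsv
```

Each subcommand writes TSV reports, a JSON summary and the fully-resolved
run configuration into its output directory.

## Packaged data

* `table1_catalog.tsv` — the 18-gene IGF pathway catalog with functional
  categories and subcellular localization.
* `table2_exclusive_variants.tsv` — 16 published case-exclusive
  rare-deleterious pathway variants with per-cohort carrier counts.
* `table3_susceptibility.tsv` — 18 autism susceptibility genes perturbed
  by virtual IGF1R/IGF2R knockout, with SFARI annotations.
* `tool_registry.yaml` — the editable 12-predictor classification
  registry.

See `docs/methods.md` for the statistical details, numerical conventions
and known limitations.
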