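# Methods

This note documents the statistical procedures, defaults, numerical
conventions and design choices behind `harmburden`, and what the
synthetic-cohort tests do and do not demonstrate about real data.

## Consensus deleteriousness scoring

Each of the 12 registered predictors maps its raw output to one of three
levels — deleterious (D), probably deleterious (P), tolerable (T) — via
the registry in `harmburden/data/tool_registry.yaml`. Categorical maps
follow each tool's published code conventions (e.g. SIFT D/T; PolyPhen-2
D/P/B with B→T; MutationAssessor H→D, M→P, L/N→T). CADD is the only
numeric tool: PHRED score compared against a cutoff of 15, with the
boundary resolved inclusive-deleterious (score = 15 → D) and no P level.
The registry is an editable file precisely because these conventions are
tool-version-dependent.

The consensus statistic over one variant's tallies is
`HARM = nD + 0.4·nP − nT`, and the two decision criteria are `nD > 0`
and `HARM > 0` (both strict). Conventions that required a decision:

* **Missing predictions** contribute to none of nD/nP/nT. The statistic
  penalizes nT, and absence of evidence is not tolerance. LRT's "U"
  (unknown) code is likewise mapped to missing, not tolerable.
* **Combination rule.** The default deleteriousness call is the
  *conjunction* of the two criteria; `either`, `crit1_only` and
  `crit2_only` are run-time switches surfaced in every report. The
  conjunction is the conservative reading of a two-criterion rule and is
  what the recovery tests exercise.

With the 12-tool registry, HARM is bounded in [−12, 12], reaches 12 only
when all 12 tools call D, and is strictly monotone under single-call
upgrades (T→P adds 1.4, P→D adds 0.6). The test suite sweeps every
(nD, nP, nT) tally with sum ≤ 12 against direct evaluation of the
formula.

## Rarity and call-rate QC

A variant is rare when its control-cohort allele frequency is **below
0.01** and the public-database condition holds over six databases
(1000g ALL/EAS, ESP6500, ExAC ALL, gnomAD controls all/EAS). The
database clause is read as *at least one* database below the threshold
(`any_db`, default); the stricter all-databases reading is available as
`db_rule="all_dbs"`. A database with no record of the variant counts as
satisfying the condition by default (absence from a population database
is evidence of rarity); both choices are explicit `RarityPolicy` fields.

The control allele frequency is (sum of alt dosages over called
controls) / (2 × called controls); missing genotypes leave both
numerator and denominator. Zero called controls is an error, not a zero.

Call rate is the fraction of *all* cohort samples with a non-missing
genotype, computed once over the joint cohort (not per group), and the
QC filter keeps variants with call rate **strictly above** 0.95 — a
variant called in exactly 19 of 20 samples (0.95) is excluded. The
filter is idempotent and is the identity on complete matrices.

Limitations: no sex-chromosome-aware frequency computation (male
hemizygosity is ignored), and depth/quality-based genotype filtering is
assumed to have happened upstream of the VCF.

## Burden testing with adaptive test selection

Per-individual burden is the count of qualifying (rare-deleterious)
variants carried (dosage ≥ 1; `alleles` mode sums dosages instead).
The case-vs-control comparison is one-tailed with the alternative fixed
to "cases exceed controls".

Test selection: Shapiro-Wilk per group and Levene across groups, each at
α = 0.05 — both normality p > α and Levene p > α → Student's t; both
normality p > α and Levene p ≤ α → Welch's t; otherwise Mann-Whitney U.
The three p-values and the chosen test are stored in the result so every
report is self-describing. Degenerate inputs: a constant group is treated
as non-normal; two constant groups fall through to Mann-Whitney with a
logged note; fully tied data report p = 1.

Mann-Whitney uses exact enumeration when both groups have ≤ 20
observations and no ties, and the normal approximation with tie
correction (and continuity correction) otherwise. On discrete burden
counts the continuity correction makes the test slightly conservative;
the Monte-Carlo calibration test measures a type-I error of ≈ 0.04–0.05
at nominal 0.05 over 2000 null replicates of Poisson burdens at
n = 100/group — the replicate count and group size chosen to give a
Monte-Carlo standard error (≈ 0.005) well inside the ±0.01 acceptance
band.

## Carrier association and multiple testing

Variant-level: a 2×2 table of carriers/non-carriers in cases and
controls. Gene-level: carrier-collapsing by default (an individual
counts once per gene if they carry any qualifying variant of it); an
allele-counting mode exists because tallying "types of variants within
each gene" admits either reading, and the mode is recorded in output
metadata. Collapsing can only enlarge the case-carrier margin, so a gene
whose case-exclusive variants have disjoint carriers attains a smaller p
than any of its single variants — asserted as a property test.

The one-tailed Fisher p is the hypergeometric upper tail
P(X ≥ case carriers) with margins fixed, computed via
`scipy.stats.hypergeom.sf`; degenerate margins (no carriers anywhere, or
an empty table) give p = 1. The test suite checks every 2×2 table with
total N ≤ 30 (46,376 tables) against an independent exact-rational
enumeration oracle to 10⁻⁹.

Benjamini-Hochberg (step-up) and Bonferroni (min(1, m·p)) are both
applied, each within its own analysis level's family (variant-level m
and gene-level m separately). BH is delegated to
`statsmodels.stats.multitest` and cross-checked against a hand step-up
oracle; BH ≤ Bonferroni pointwise always holds.

No covariate adjustment is performed anywhere: genotype is not
confounded by age or sex in this design, and the association tests are
exact conditional tests.

## Exclusivity screening and reports

The screen retains qualifying variants with ≥ 1 carrier in a case group
and 0 carriers in every group named by the policy: controls only for a
plain case-control cohort (default), and controls + siblings + fathers
+ mothers for family-structured cohorts. The policy is echoed in every
report. A second entry point replays *published* exclusive-variant
tables, which carry per-cohort carrier counts rather than genotypes;
replaying the packaged 16-row table restricted to IGF1R and the SPARK
ASD cohort yields 9 variants.

Category summaries report per-category percentages rounded
half-away-from-zero to one decimal, so two categories holding 4 of 26
variants each both print 15.4% (the consistent rounding of 15.38%);
rounded percentages always sum to 100 ± 0.2. The catalog stores the
category assignment of the eight downstream signaling genes (AKT1,
PIK3R1, RPS6KB1 under PI3K/AKT; MAPK3, MAPK1, MAP2K1, MAP2K2, EIF4EBP1
under MAPK) in the fixture rather than in code, because the split of the
two translation-control factors between the branches is a documented
judgment call, not a computable fact.

Gene-set overlap normalizes symbols to upper case and reports mutual
percentages; a hypergeometric enrichment p is computed only when the
caller supplies a universe size and is labeled supplementary, since the
headline overlap statements are descriptive.

## The synthetic cohort generator

The generator emulates the *statistical shape* of a pathway-panel WES
cohort, with defaults chosen as the study conditions the analysis was
designed around:

| parameter | default | rationale |
|---|---|---|
| n_cases / n_controls | 263 / 294 | the case-control cohort geometry |
| af spectrum | log-uniform on [1e-4, 0.05] | spans private to borderline-common panel variants |
| deleterious_fraction | 0.36 | the observed deleterious share of rare panel variants (26/72) |
| tool_concordance | 0.9 | per-tool accuracy of modern predictors on clear-cut variants |
| p_level_fraction | 0.2 | share of equivocal calls emitted as P |
| missing_rate | 0.02 | typical post-QC genotype missingness |
| db_noise_sigma / db_missing_rate | 0.3 / 0.1 | population-database AFs scatter around the cohort AF; rare variants are often absent from databases |

Genotypes are Hardy-Weinberg draws at the variant's true frequency.
Tool calls are per-tool Bernoulli(concordance) correct-level calls, with
a `p_level_fraction` of discordant calls on deleterious variants (and of
misses on benign ones) emitted as P where the tool has a P level — so
E[nD] = 12 × concordance for truth-deleterious variants. Database
frequencies are the true frequency times log-normal noise, truncated to
[0, 1]. A single root seed feeds named substreams (frequencies,
genotypes, tool calls, database noise, missingness, planting) so one
component's draw count does not perturb the others; identical configs
are bit-identical.

Planted effects and the truth ledger:

* **Prevalence gap** — each case independently gains, with probability
  `prevalence_gap`, a heterozygous call at one random truth-qualifying
  variant; case prevalence rises by ≈ gap·(1 − base prevalence).
* **Case-exclusive variants** — chosen variants are zeroed outside cases
  and given exactly `exclusive_carrier_count` case carriers; they are
  always truth-deleterious and truth-rare. When exclusives are planted,
  the generator additionally gives one control carrier to any *other*
  variant that came out case-only by chance, so the ledger is the
  complete case-exclusive set and recovery can be asserted exactly.
  Exclusivity planting runs after gap planting so the guarantee holds
  under combined effects.

What the generator does **not** emulate — and therefore what passing
recovery tests do *not* show about real cohorts: linkage disequilibrium
between variants, realistic site-frequency spectra, population
stratification, relatedness, pedigree transmission or de-novo events
(family groups carry labels only), batch effects in missingness, and
correlated errors across predictors (real tools share training data, so
their 12 votes are far from independent; effective evidence per variant
is overstated at any fixed concordance).

## Problem sizes in tests and acceptance runs

Monte-Carlo checks use: 2000 replicates (n = 100/group) for burden-test
type-I calibration; 200 replicates of full cohort simulation at
n = 300/group and 30 variants for prevalence-gap power (0.15 gap) and
null calibration; 1000 simulated variants for HARM classification
accuracy at concordance 0.9; 60 replicates × 20 variants for the
planted-enrichment ranking property. These sizes keep the whole suite
under a minute of Monte-Carlo time while leaving the Monte-Carlo standard
error of each calibrated rate several times smaller than the tolerance
asserted on it.

## Known limitations

* The headline cohort-level counts of the motivating study (72 rare
  variants, 26 deleterious, ~25% case carrier prevalence) require the
  original genotype data and are not reproduced here; they inform
  simulator defaults only.
* Gene-level allele-counting mode uses 2 × variants × group size as the
  allele margin, which treats variants as independent trials; it is
  reported for completeness, not preferred.
* The adaptive test's selection step and the subsequent test are not
  independent; the measured (slightly conservative) type-I error of the
  combined pipeline, not of the individual tests, is what the
  calibration test certifies.
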