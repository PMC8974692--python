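# Methods

## Scope and model

The package re-implements a rule-based translational pipeline: it does not
fit a statistical model to data but applies declared decision rules —
weighted evidence aggregation, thresholded selection, multiplicity-corrected
screens — whose behaviour is fully specified by a small number of
parameters. Those rules, their defaults and the numerical choices behind
them are documented here.

## Evidence weighting and candidate selection

Evidence for a signal–gene pair is grouped into fourteen categories: ten
database categories (GTEx respiratory and blood eQTLs and sQTLs,
Open-Target-Genetics respiratory and blood eQTLs, V2G assignment,
colocalization study, HaploReg eQTLs, tagged functional variants), three
U-BIOPRED airway eQTL compartments (bronchial brush, bronchial biopsy,
nasal brush) and literature association. Default weights are 1 per
database/literature category and 2 per U-BIOPRED compartment; each category
contributes at most once (presence/absence semantics — the packaged score
table is only reproducible under this reading, e.g. a gene with eQTLs in
five GTEx respiratory tissues still collects one point there).

Per-source significance rules are applied before scoring: *P* < 0.05
(strict) for eQTL/sQTL categories, H4 > 0.8 (strict) for colocalization,
presence for V2G, tagged-variant and literature categories.

**The printed scheme total.** The published weighting table prints a "total
possible score" of 16, but its listed weights sum to 17 (eleven singles
plus three doubles), and the packaged score table contains base scores of
11 — attainable only if eleven single-weight categories are scored. The
package follows the listed weights: `max_possible_score()` returns their
sum, 17. The printed 16 appears to be an arithmetic slip and is not
reproduced.

**Selection.** Genes with total s ≥ 3 (inclusive) are candidates; a signal
with none falls back to its unique highest-scoring gene, and a tie there is
reported as an ambiguity error rather than silently broken — the selection
convention never had to break such a tie, so the package refuses to invent
one. Literature overrides replace a signal's selection entirely. One pair
in the packaged table (rs776111176:HLA-DOB, s = 4) satisfies the threshold
but is absent from the published 37-gene candidate set; the package selects
it and attaches a `published-set mismatch` annotation instead of dropping
it, since the exclusion rule is undocumented.

**Inconsistent published rows.** For one signal (rs776111176) the published
totals equal base + UB rather than base + 2 × UB, i.e. the printed UB
column there already holds points rather than compartment counts. The
fixture stores all totals verbatim; recomputation (and the acceptance
checks) are restricted to the weight-2-consistent rows, which are 99 of the
109 rows.

## LD proxies

A sentinel absent from a dataset is replaced by the available linked
variant maximising r², subject to r² ≥ 0.2 (inclusive, reading "minimum
r² = 0.2" at face value). Ties at equal r² are broken by the
lexicographically smallest rsid — the published analysis shows no tie, so
this is a determinism convention, not inferred intent. Failure carries the
best sub-threshold r² so reports can state how close a signal came to being
interrogable.

## PheWAS screen

The per-trait level is α/n_traits at full precision (0.05/778 =
6.4267 × 10⁻⁵); the conventional display truncates the significand to three
digits (6.42 × 10⁻⁵), and only the display does so — comparisons use the
full value. Retention is strict (p < threshold), so the threshold itself is
non-significant. Protective calls (odds ratio < 1, strictly — OR = 1 is not
protective) are made only for records that carry an odds ratio; quantitative
traits are never flagged. Trait-to-group mapping is a user-supplied YAML
file because the published grouping was manually curated.

## Differential expression

Default group design: 20 controls, 50 mild-moderate and 38 severe subjects
(airway epithelium); the blood design (87/77/246) is available as a
constant. Per gene the Shapiro-Wilk test at α = 0.05 gates every group;
Welch's ANOVA runs only when all groups pass, otherwise Kruskal-Wallis
(mid-ranks, standard tie correction, chi-square reference with k−1 df). A
constant-valued group is treated as non-normal (normality is degenerate
there). The gate α is the package's choice — the published analyses do not
state one, and at 0.05 the blood-style data route overwhelmingly through
the rank test, matching the reported outcome that only 2 of 18 blood genes
took the normal path. A `force_kruskal` switch pre-commits to the
non-parametric path for analyses that gate nothing.

Welch's ANOVA is implemented directly (heteroscedastic F* with
Welch-Satterthwaite denominator df) and cross-checked in the tests against
pingouin and the two-group identity F* = t²_Welch. All-identical input to
Kruskal-Wallis returns (H = 0, p = 1) rather than an error.

**Two-stage FDR.** The Benjamini-Krieger-Yekutieli two-stage step-up:
stage 1 is a linear step-up at q′ = q/(1+q); with r₁ rejections the null
count is estimated as m₀ = m − r₁; r₁ = 0 rejects nothing and r₁ = m
rejects everything; otherwise stage 2 re-runs the step-up at q′·m/m₀.
Adjusted q-values follow the standard convention (BH-adjusted p scaled by
m₀/m and by 1+q, clipped to 1, monotone by cumulative minimum), so the
rejection flags coincide exactly with `q_adj ≤ q` at the nominal level; the
alternative reading "smallest q at which the hypothesis is rejected" is
implicit (m₀ itself depends on q) and was deliberately not used. The
implementation is validated against statsmodels'
`fdrcorrection_twostage(method="bky")` and, in simulation, holds the
empirical FDR below the nominal 5% on independent p-values
(measured ≈ 4.4% at m = 1000 with 80% uniform nulls and Beta(0.1, 1)
alternatives over 2000 replicates — the acceptance script recomputes this).

Post-hoc pairwise comparisons use the omnibus family (Mann-Whitney U or
Welch t) and are computed only for discoveries; by default each gene's
pairwise p-values pass through the same two-stage procedure
(`posthoc_adjust="per_gene"`), with a raw option, because the published
figures do not state their post-hoc correction scope.

## Enrichment

The tail probability is hypergeometric P[X ≥ k]; the default `ease` mode
replaces k by max(k−1, 0) — the conservative variant used by DAVID-style
tools, which the packaged enrichment table derives from. Fold enrichment is
(k/n)/(K/N); k = 0 gives FE = 0 and p = 1. Term-level FDR is
Benjamini-Hochberg. The packaged enrichment table is a reporting fixture
for the count/percent columns only: its FE and p columns depend on a
database background that is not published, so they are not recomputation
targets. The default background is the union of all term genes;
user-supplied backgrounds are supported, and query genes outside the
background are dropped with a warning.

## Profiles and colocalization

The enriched/enhanced expression rule is the fourfold criterion applied
inclusively: class c qualifies iff value(c) ≥ 4 × max(other classes) and
value(c) > 0 (the positivity guard keeps an all-zero profile from flagging
every class; for fold > 1 at most one class can ever qualify). The
published distinction between "enriched" and "enhanced" is collapsed into
this single flag, as the source methods collapse them. Heatmap transforms
use log₁₀(x + 1); the unit pseudocount maps zero pTPM to zero, the standard
choice for TPM-scale data whose zero handling is otherwise unstated.
Colocalization summaries take the sample median of H4 per gene and tissue
class (midpoint convention for even counts) and call linkage strictly
(median > 0.8, so a median of exactly 0.8 is unlinked, matching the strict
H4 > 0.8 rule used at the scoring stage); genes without records are
`no_data`, never `neither`.

## Drug triage

Scored-database records are retained when interaction score > 1.0
(strictly; exactly 1.0 is excluded). Trial-only records have no score and
are never counted as scored interactions. The queried universe of the
packaged table is 42 genes: the 37 candidates plus the five
interaction-predicted genes (CD274, IL37, IRAK4, PDCD1LG2, ZAP70). On this
table 14 genes carry at least one scored interaction; the companion
abstract-level figure of 11 druggable candidate genes is not reproducible
from the table under any partition tried, so 14-of-42 is the quantity the
package locks and the discrepancy is surfaced rather than resolved.

## Synthetic data

Generators emulate the statistical shape of the pipeline's inputs, not
their biology:

- **LD blocks** — r²(i, j) = ρ^(2|i−j|) with per-position correlation decay
  ρ (default 0.9), a closed form spanning the realistic r² range of the
  packaged proxy table; no recombination-map realism.
- **Evidence tables** — per signal one designated causal gene draws each
  category independently at probability 0.8, decoys at 0.05; generated
  p-values sit below 0.05 and H4 above 0.8 so records survive significance
  filtering by construction. At these rates scoring plus selection recovers
  the designated gene for ≥ 90% of signals (measured 25/25 at the default
  seed).
- **Expression** — log-normal per-gene baselines (log-mean U(4, 7),
  log-sd U(0.2, 0.5)); planted genes receive an additive shift of
  `effect_sd_units` × the gene's theoretical baseline SD in both asthma
  groups. Default effect 2 SD over 100 genes with 10 planted; 3-SD effects
  at the default design are detected with power > 0.95 through the full
  gate/test/FDR pipeline.
- **p-value ensembles** — ⌊π₀m⌋ uniform nulls plus Beta(a, b) alternatives
  with truth labels.

Seeding: one integer seed, fanned out through `SeedSequence(seed,
spawn_key=(stream,))` with a fixed stream index per generator.

What the generators do not emulate — array normalisation artefacts,
correlated genes, batch effects, linkage between evidence categories,
realistic trait correlation in PheWAS tables — bounds what green tests
show: they validate the decision rules and error control under the stated
independence assumptions, not robustness to the dependence structure of
real cohort data.

## Pipeline and reproducibility

Stages execute in a fixed order (proxy → score → phewas → de → enrich →
profile → drugs), each independently switchable; a failed stage aborts with
its name and leaves earlier outputs untouched. The run report (JSON)
records per-stage row counts, thresholds in force, candidate provenance and
a configuration hash that excludes the output directory, so identical
analyses are byte-identical wherever they are written. Problem sizes used
by the test-suite simulations (100–250 genes, 15–20 replicates for
FDR/power averages, 2000 replicates in the acceptance FDR run, 10⁵
permutations for the rank-test oracle) were chosen to make Monte-Carlo
error small relative to the margins being asserted.

## Known limitations

- Colocalization posteriors (H4) are consumed, never computed.
- No allele-orientation harmonisation across evidence sources: effect signs
  are taken as provided, assumed pre-oriented to the risk allele.
- The enrichment stage cannot reproduce published FE/p values without the
  original database background.
- The chi-square reference for Kruskal-Wallis is an approximation; at very
  small group sizes (≤ 3 per group) it deviates noticeably from the exact
  permutation distribution, as the oracle tests document.
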