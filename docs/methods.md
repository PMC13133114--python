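# Methods

This note documents the statistical procedures, parameter choices and
known limitations of the screening cascade, in the order the method runs.

## Problem setting and assumptions

The cascade screens hypotheses "feature *x* is associated with binary
outcome *y*, with a given direction" over a participant-level table. It
assumes: a binary target; mixed numeric/binary features; baseline
covariates age (years), sex (0/1) and BMI (kg/m²) available for
confounding control; and feature names/descriptions that are meaningful
text (they drive entity linking and literature queries). The cascade is a
*screen*, not an inference procedure: its output is a prioritized reading
list, and its filters are deliberately tuned for recall of plausible
novelty, not for error control.

## Preparation

* **Sparsity floor** (`prep.min_nonmissing`, default 30 observed values):
  features below the floor carry too little information for any downstream
  test and are dropped before imputation.
* **Imputation** is single mean-imputation plus a binary `__missing`
  indicator per affected feature. Flags are only created when missingness
  exists, to avoid constant columns. Because imputed values equal the
  observed mean, each flag is exactly uncorrelated with its parent column,
  so the subsequent correlation screen never pairs them spuriously.
  Missingness is assumed non-informative for the *values*; any
  informative-missingness signal is still available to the utility stage
  through the flags.
* **Correlation deduplication** (`prep.corr_threshold`, default 0.9
  absolute Pearson): a greedy first-seen scan in declared column order
  keeps the earlier feature of any violating pair. The greedy order rule
  is a deliberate determinism choice: it makes dedup reproducible and
  auditable (each drop logs the kept partner and r). Constant columns are
  excluded from the screen and retained with a warning.
* **IPW downsampling** (off by default; `ipw_ratio` 9): a regularized
  logistic propensity model P(y=1 | age, sex, BMI) on standardized
  covariates; controls are drawn without replacement with probability
  proportional to predicted propensity until the controls:cases ratio is
  reached. Cases are never touched. If controls are already at or below
  the ratio the step is a logged no-op. The prep pipeline is idempotent:
  running it twice changes nothing.

## Utility filter

Three scores per feature, combined as a disjunction by default
(`utility.mode = any`; conjunction available):

* **p-value**: Welch two-sample location test between outcome classes for
  continuous features; chi-square test of independence for features with
  ≤ 5 distinct values, replaced by Fisher's exact test for 2×2 tables
  with any expected cell < 5. Compared strictly `< θ_p` (default 0.2).
  The test choice matters little at so lenient a threshold, which is why
  a standard battery is used rather than a single test.
* **Mutual information**: plug-in estimator on a quantile-binned joint
  table (default 10 bins; discrete features used as-is), in nats,
  compared `≥ θ_MI` (default 10⁻³). The plug-in estimator is biased
  upward at small n but reproducible and exactly checkable against the
  direct contingency-table sum.
* **Model importance**: LightGBM classifier in 5-fold stratified
  cross-validation (100 trees, single-threaded deterministic mode);
  importance is the mean absolute per-sample TreeSHAP contribution on
  held-out folds, compared `≥ θ_FImp` (default 10⁻⁴). Attribution
  additivity (contributions + base value = raw margin) is verified in
  tests to 10⁻⁶.

Constant features score p = 1, MI = 0. Thresholds are monotone: loosening
any threshold can only grow the pass set (property-tested).

## Concept linking and KG novelty

Entity linking is behind a provider interface. The bundled offline
provider links by Jaccard token overlap against an entity lexicon and
embeds text as L2-normalized hashed character-3-gram count vectors; it is
deterministic byte-for-byte, which the test suite relies on. It performs
no abbreviation expansion or fuzzy morphology — production use should
substitute a trained biomedical linker/embedder behind the same
interface.

Gates, in order (order provably irrelevant to the outcome): confidence
≥ 0.88, at most 3 entities per feature (ties at the cut broken by lower
entity id); category exclusion by case-insensitive regex over
category/name; similarity gate removing links with cosine < 0.1 and
flagging ≥ 0.4 as strongly linked. Similarity is computed against the
entity's canonical name (not the matched surface span).

The knowledge graph ignores predicate direction and type (undirected
adjacency); parallel edges merge keeping max evidence count and earliest
first-report year, then edges with < 2 unique citations are dropped as
probable extraction noise. A feature is *known* iff all its linked
entities are 1-hop from a target entity, or any strongly linked entity
is. Unlinked features are treated as novel-by-default: the filter
prioritizes precision in exclusion, accepting that poor linkage coverage
inflates apparent novelty (a documented failure mode, see Limitations).

Temporal validation splits edges at a cutoff year (each edge carries an
explicit `first_year`; real predication databases would need this derived
from citation metadata). The reported share of post-cutoff features uses
the 1-hop-linked feature count as denominator, with a 95% Wilson score
interval.

## Literature novelty

The decision uses four counts: feature hits n_x, target hits n_y,
co-mentions n_xy, corpus size N (default 37,000,000 documents,
configurable). Retention reasons, checked in order: `rare-feature`
(n_x < 20 — recently coined terms and dataset-specific variable names),
`few-comentions` (n_xy < θ_lit = 4), `underrepresented` (one-sided
hypergeometric tail P(X ≤ n_xy) < θ_pval = 0.4, i.e. a one-way Fisher
exact test with alternative "less" on the document-universe 2×2 table).
Otherwise the pair is `known` and removed. Retention is monotone in n_xy
at fixed margins. The offline provider is a CSV-backed count table;
unknown terms count 0 (hence are retained as rare — conservative in the
novelty direction).

## LLM annotation and selection

Prompts are plain-text config templates with slots for the candidate, its
direction and statistics, and an optional retrieved-context block;
wording requests step-by-step reasoning and a machine-parseable answer
block with three 1–4 integer scores and one-sentence rationales.
Retrieval is Okapi BM25 (k1 = 1.5, b = 0.75) over an indexed corpus,
top 32 passages for the query "feature + target". Parsing failures are
retried twice, then the candidate is flagged unannotated and excluded
from selection — an explicit failure surface rather than a silent
default. The ordering key ("confidence") defaults to the overall
interestingness score; the selection keeps scores > 2, sorts by
confidence, then model importance, then id, and truncates to 30. A
second-pass overall scoring by a stronger model is the same annotate step
with a different provider handle, not a separate code path.

## Evaluation machinery

* Wilson score intervals (boundaries snapped exactly to 0/1 at k = 0 or
  k = n); percentages round to nearest integer for reporting.
* Two-sided Fisher exact tests sum hypergeometric point masses ≤ the
  observed table's.
* Cohen's kappa is unweighted on the raw 1–4 scores; the degenerate case
  (both raters constant and equal) is defined as 1.0 with a warning.
* Real-vs-distractor comparisons use Welch (unequal-variance) t-tests.
* NDCG uses linear gain in the 1–4 rating (an exponential-gain variant is
  a parameter switch) with 1/log₂(rank+1) discount; MRR binarizes at
  rating ≥ 3.
* Distractor injection samples ⌈frac·|real|⌉ utility-rejected features
  without replacement and shuffles, deterministic under seed.

## Synthetic study world

The generator emulates the statistical structure the cascade assumes, at
toy scale: a logistic outcome model over planted features (effects in
log-odds per SD), confounders entering both the outcome and a proxy
feature linearly, MCAR missingness (the weakest testable mechanism —
informative missingness is deliberately not simulated), an intercept
solved by bisection to hit the requested prevalence, and a feature mix of
~30% binary / 70% continuous nulls. Specs with fewer than 10 expected
cases are rejected. The toy KG writes known feature–target edges with
citation counts and years plus random background edges that can never
recreate a feature–target pair. Literature counts are CRC-derived (no RNG
state), with overrides for planted known pairs.

What it does not emulate: correlated feature blocks beyond the planted
confounder proxies, nonlinear or interaction effects, informative
missingness, label noise in diagnoses, time-to-event structure, or
realistic entity-linking ambiguity. A passing recovery study therefore
shows the cascade's plumbing and decision rules are correct under its own
assumptions — not that the filters are well-calibrated on real cohort
data.

The canonical recovery study (`recovery_study_spec`) uses n = 5000
participants, prevalence 0.15, one novel planted factor (+1.2
log-odds/SD), nine KG-known and four literature-known planted factors
(+1.0 each, ~20% of the 64-column feature table), fifty nulls and an age
confounder, evaluated over ten seeds. These sizes keep a full ten-seed
study around a minute on one CPU while leaving the planted effect
overwhelmingly detectable.

## Numerical and reproducibility choices

All randomness derives from one master seed via CRC32-derived per-stage
seeds (< 2³¹). LightGBM runs single-threaded in deterministic mode.
Sorts that can tie (link confidence, BM25 scores, selection) carry
explicit deterministic tie-breaks. Re-running a pipeline with the same
config and seed reproduces outputs byte-for-byte; `run_meta.json` records
a SHA-256 config hash that changes iff any config value changes.

One discrepancy worth recording: an exact two-sided Fisher test on the
aggregated baseline-comparison table [[14,31],[6,39]] yields p = 0.074.
A commonly quoted 0.043 for such a table corresponds to an uncorrected
chi-square statistic, not the exact test; this package reports the exact
value.

## Known limitations

Novelty is only as good as the knowledge sources: sparse KG coverage or
failed linking inflates novelty (false "novel" labels), while lexicon
noise can suppress genuine novelty. Single mean-imputation understates
variance for the univariate tests. The plug-in MI estimator is biased at
small n. The sensitivity sweep (`threshold_sensitivity`) varies the
p-value criterion alone by default, because under a disjunctive filter
the MI/FImp criteria mask θ_p entirely. The scripted LLM provider tests
the annotation plumbing, not judgment quality — alignment between any
real model's scores and expert opinion must be measured with the
evaluation module on annotated output.
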