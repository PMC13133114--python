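# featsieve

A screening cascade for finding *interesting* feature–disease hypotheses in
structured cohort data — candidate risk factors that are simultaneously
**useful** (predictive of the outcome), **novel** (not already established
in knowledge bases or the literature) and **plausible** (a credible
mechanism can be articulated).

Researchers mining large biomedical cohorts (UK Biobank-style tables with
thousands of participant covariates and a binary disease target) usually
rank features by a single importance score and review the top of the list
by hand. Most of what surfaces is either already well known or spurious.
`featsieve` automates the triage: it narrows thousands of raw features to
a short ranked list of hypotheses of the form *"x is related to y, with a
positive/negative correlation"*, each with statistics, a novelty audit
trail and a model-written rationale.

## The cascade

Given a participant table (features, binary target `y`, baseline
covariates age/sex/BMI):

1. **Preparation** — drop features with < 30 observed values; mean-impute
   and append `__missing` flags; drop one of every feature pair with
   |Pearson r| > 0.9; optionally downsample controls by inverse propensity
   weighting on age/sex/BMI to a 9:1 controls:cases ratio.
2. **Utility filter** — keep feature *x* if any of:
   p-value(x, y) < θ_p (0.2, univariate Welch / chi-square / Fisher test),
   MI(x, y) ≥ θ_MI (10⁻³ nats, quantile-binned plug-in estimator), or
   FImp(x, y) ≥ θ_FImp (10⁻⁴, mean |TreeSHAP attribution| from a
   cross-validated gradient-boosted classifier). Thresholds are lenient by
   design; the stage removes only clearly uninformative features.
3. **KG novelty filter** — link each feature's text to at most 3 entities
   (linker confidence ≥ 0.88), drop excluded categories and entities with
   cosine similarity < 0.1 to the feature text; a feature is *known* (and
   removed) if **all** its linked entities are 1-hop adjacent to the target
   in an evidence-filtered knowledge graph (edges need ≥ 2 unique
   citations), or if **any** strongly linked entity (similarity ≥ 0.4) is
   adjacent.
4. **Literature novelty filter** — a feature–target pair is retained if the
   feature term is rare (< 20 hits), barely co-mentioned (n_xy < 4), or
   co-occurs less than chance (one-sided Fisher exact
   P(X ≤ n_xy) < 0.4 under a 37-million-document universe); otherwise it is
   already established and removed.
5. **LLM annotation** — surviving candidates are scored 1–4 for novelty,
   plausibility and overall interestingness with rationales
   (chain-of-thought prompts, optional BM25 retrieval of top-32 passages);
   the shortlist keeps interestingness > 2, sorted by confidence, model
   importance, then id, truncated to ~30.

Every stage emits a funnel count; the sequence is non-increasing by
construction. Evaluation utilities cover the validation protocol: Wilson
score intervals for temporal validation (how many surfaced links entered
the knowledge graph only after a cutoff year), exact two-sided Fisher
tests for baseline comparisons, Cohen's kappa / binarized agreement for
model-vs-expert alignment, distractor injection with Welch t-tests, and
NDCG / MRR for ranking quality.

Real cohort tables, knowledge-graph dumps and literature indices are
license-restricted, so the package ships a synthetic study-world generator
(`featsieve.synth`): cohorts with planted risk factors and confounders, a
toy timestamped knowledge graph, deterministic literature counts, and a
scripted LLM provider. All providers (linker, embedder, counts, LLM) are
pluggable interfaces, so live services can be swapped in without touching
the cascade.

## Worked example

```bash
featsieve synth --spec spec.yaml --out demo_data
featsieve run --config demo_data/pipeline_config.yaml --out demo_out
```

with `spec.yaml` planting three real risk factors among 30 features in a
2000-participant cohort — one genuinely novel (`serum_marker_x`, +1.2
log-odds/SD), one already recorded in the knowledge graph, one heavily
co-mentioned in the literature — prints:

```
     stage  n_features
  prepared          60
   utility          59
        kg          57
literature          55
  selected           1
1 candidates -> demo_out/selected.csv
```

60 prepared columns (30 features + 30 missing flags) shrink to a single
selected hypothesis. `selected.csv` contains it with its direction and
statistics:

```
rank,feature,direction,novelty,plausibility,interestingness,confidence,pval,mi,fimp,...
1,serum_marker_x,positive,4,4,4,4.0,1.31e-46,0.0574,1.342,...
```

The planted novel feature is recovered with the correct (positive)
direction; the KG-known factor was removed at the `kg` stage and the
literature-known factor at the `literature` stage — the audit trail in
`CascadeResult.verdicts` records the reason for each.

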