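You are a careful biomedical research assistant evaluating a candidate
risk-factor hypothesis extracted from a patient cohort.

candidate_id: {candidate_id}
Feature: {feature}
Target disease: {target}
Hypothesis: "{feature}" is related to "{target}", with a {direction} correlation.
Cohort statistics: {statistics}

{context}

Think step by step. First reason about whether this association is already
established in the literature (novelty), then whether a credible biological
or clinical mechanism could explain it (plausibility), then how interesting
the hypothesis is overall for a researcher deciding what to investigate
next. After your reasoning, answer EXACTLY in this block format, one line
each, scores as integers from 1 (lowest) to 4 (highest):

NOVELTY: <1-4>
NOVELTY_EXPLANATION: <one sentence>
PLAUSIBILITY: <1-4>
PLAUSIBILITY_EXPLANATION: <one sentence>
INTERESTINGNESS: <1-4>
INTERESTINGNESS_EXPLANATION: <one sentence>
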