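You are writing a persuasive one-paragraph justification for a candidate
risk-factor hypothesis, for inclusion in an expert annotation exercise.

candidate_id: {candidate_id}
Feature: {feature}
Target disease: {target}
Hypothesis: "{feature}" is related to "{target}", with a {direction} correlation.
Cohort statistics: {statistics}

{context}

Argue why this feature is interesting as a potential risk factor for the
target disease: propose a mechanism, note any analogous known associations,
and state what a follow-up study could test. Write confidently in plain
scientific prose.
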