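"""Evaluation machinery for the screening cascade.

Everything needed to evaluate a run the way the study protocol does:
Wilson score intervals for temporal-validation proportions, exact
two-sided Fisher tests for baseline comparisons, Cohen's kappa and
binarized agreement for model-vs-expert alignment, distractor injection
for annotator-discrimination studies, Welch t-tests for real-vs-distractor
score comparisons, and NDCG / MRR for ranking quality against graded
expert relevance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from ._common import derive_seed, logger


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    Well-behaved at the boundaries: the lower bound is exactly 0 for
    k = 0 and the upper exactly 1 for k = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return lo, hi


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_two_sided(table: ContingencyTable2x2 | list | np.ndarray) -> float:
    """Exact two-sided Fisher p: mass of tables no more probable than observed."""
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("empty margin in 2x2 table; p = 1.0")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def cohens_kappa(r1, r2) -> float:
    """Unweighted Cohen's kappa between two raters' categorical scores.

    If both raters are constant and identical, chance agreement is 1 and
    kappa is undefined; by convention 1.0 is returned with a warning.
    """
    r1, r2 = np.asarray(r1), np.asarray(r2)
    if len(r1) != len(r2):
        raise ValueError("rater vectors must have equal length")
    if len(r1) == 0:
        raise ValueError("empty rater vectors")
    cats = np.union1d(r1, r2)
    if len(cats) == 1:
        logger.warning("both raters constant and equal; kappa = 1.0 by convention")
        return 1.0
    return float(cohen_kappa_score(r1, r2))


def binarized_agreement(model_flags, human_flags) -> float:
    """Fraction of items on which binarized model and human labels agree."""
    m, h = np.asarray(model_flags), np.asarray(human_flags)
    if len(m) != len(h):
        raise ValueError("flag vectors must have equal length")
    if len(m) == 0:
        raise ValueError("empty flag vectors")
    return float(np.mean(m == h))


def inject_distractors(
    real: list,
    discarded_pool: list,
    frac: float = 0.2,
    seed: int = 0,
) -> tuple[list, dict]:
    """Mix ceil(frac * |real|) utility-rejected distractors into a candidate set.

    Distractors are sampled without replacement from the pool of features
    that failed the utility filter, the combined list is shuffled, and a
    hidden id -> is_distractor map is returned for later unblinding.
    Deterministic under ``seed``.
    """
    n_d = math.ceil(frac * len(real))
    if n_d > len(discarded_pool):
        raise ValueError(f"distractor pool too small: need {n_d}, have {len(discarded_pool)}")
    ids = [_candidate_id(c) for c in list(real) + list(discarded_pool)]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate candidate ids across real and pool")
    rng = np.random.default_rng(derive_seed(seed, "distractors"))
    if n_d == 0:
        return list(real), {_candidate_id(c): False for c in real}
    chosen = [discarded_pool[i] for i in rng.choice(len(discarded_pool), size=n_d, replace=False)]
    combined = list(real) + chosen
    labels = {_candidate_id(c): (i >= len(real)) for i, c in enumerate(combined)}
    order = rng.permutation(len(combined))
    return [combined[i] for i in order], labels


def _candidate_id(c) -> str:
    return str(getattr(c, "feature_id", c))


def welch_ttest(a, b) -> float:
    """Two-sided Welch t-test p-value comparing group means."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False)[1])


def ndcg(ranked_relevances, gain: str = "linear") -> float:
    """Normalized discounted cumulative gain of a ranked relevance list.

    Gains are the raw graded relevances (1-4 expert ratings) by default;
    ``gain="exp"`` switches to 2^rel - 1.  Discount is 1/log2(rank + 1).
    All-zero relevance is defined as 0 with a warning.
    """
    rel = np.asarray(ranked_relevances, dtype=float)
    if len(rel) == 0:
        raise ValueError("empty ranking")
    g = (2.0**rel - 1.0) if gain == "exp" else rel
    if g.sum() == 0:
        logger.warning("all-zero relevance; ndcg = 0")
        return 0.0
    disc = 1.0 / np.log2(np.arange(2, len(g) + 2))
    ideal = np.sort(g)[::-1]
    return float((g * disc).sum() / (ideal * disc).sum())


def mrr(ranked, threshold: int = 3) -> float:
    """Reciprocal rank of the first relevant item.

    Boolean input is used as-is; numeric input is binarized at
    ``rating >= threshold``.  No relevant item yields 0 with a warning.
    """
    arr = np.asarray(ranked)
    relevant = arr if arr.dtype == bool else arr >= threshold
    hits = np.flatnonzero(relevant)
    if len(hits) == 0:
        logger.warning("no relevant item in ranking; mrr = 0")
        return 0.0
    return float(1.0 / (hits[0] + 1))


def score_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Real-vs-distractor score comparison over an annotation table.

    ``records`` columns: novelty, plausibility, utility, interestingness
    (1-4 scores) plus ``is_distractor``.  Returns per-dimension group
    means and the Welch two-sided p-value.
    """
    rows = []
    for dim in ("novelty", "plausibility", "utility", "interestingness"):
        if dim not in records.columns:
            continue
        real = records.loc[~records["is_distractor"], dim]
        dist = records.loc[records["is_distractor"], dim]
        rows.append(
            {
                "dimension": dim,
                "mean_real": float(real.mean()),
                "mean_distractor": float(dist.mean()),
                "pvalue": welch_ttest(real, dist),
            }
        )
    return pd.DataFrame(rows)
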