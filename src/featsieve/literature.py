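"""Literature-based novelty filter.

Mirrors the question a researcher asks first: "are there already papers
about x and y?".  Given hit counts for the feature term (n_x), the target
term (n_y), their co-mention count (n_xy) and the corpus size N, a
feature-target pair is *retained* (treated as not yet established) when

* the feature term is rare (n_x < 20 hits: recently coined terms and
  cohort-specific variable names fall here), or
* the pair is barely co-mentioned (n_xy < theta_lit = 4), or
* the pair co-occurs *less* often than chance (one-sided Fisher exact /
  hypergeometric tail P(X <= n_xy) < theta_pval = 0.4 under a document
  universe of N papers).

Otherwise the pair is considered established and filtered out.  The
thresholds are deliberately relaxed: the filter should only drop clearly
well-documented associations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

from pydantic import BaseModel, Field
from scipy import stats

#: default document-universe size, roughly the biomedical corpus scale
DEFAULT_CORPUS_SIZE = 37_000_000


@dataclass(frozen=True)
class LiteratureCounts:
    n_x: int
    n_y: int
    n_xy: int
    N: int

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_xy, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_xy > min(self.n_x, self.n_y):
            raise ValueError("co-mention count exceeds a marginal count")
        if max(self.n_x, self.n_y) > self.N:
            raise ValueError("term count exceeds corpus size")


class LitConfig(BaseModel):
    theta_lit: int = Field(default=4, gt=0)
    theta_pval: float = Field(default=0.4, gt=0)
    min_feature_hits: int = Field(default=20, gt=0)
    corpus_size: int = Field(default=DEFAULT_CORPUS_SIZE, gt=0)


def underrepresentation_pvalue(counts: LiteratureCounts) -> float:
    """One-sided under-representation p-value for the co-mention count.

    The 2x2 table [[n_xy, n_x - n_xy], [n_y - n_xy, N - n_x - n_y + n_xy]]
    is tested with alternative "less"; equivalently the hypergeometric
    lower tail P(X <= n_xy) for X ~ Hypergeom(N, n_x, n_y).
    """
    c = counts
    table = [[c.n_xy, c.n_x - c.n_xy], [c.n_y - c.n_xy, c.N - c.n_x - c.n_y + c.n_xy]]
    return float(stats.fisher_exact(table, alternative="less")[1])


def literature_filter(
    counts: LiteratureCounts, config: LitConfig | None = None
) -> tuple[bool, str]:
    """Retain/drop decision with a reason code.

    Reasons: ``rare-feature`` (n_x below the hit floor), ``few-comentions``
    (n_xy below theta_lit), ``underrepresented`` (one-sided p below
    theta_pval), ``known`` (none of the above -> filtered out).
    """
    config = config or LitConfig()
    if counts.n_x < config.min_feature_hits:
        return True, "rare-feature"
    if counts.n_xy < config.theta_lit:
        return True, "few-comentions"
    if underrepresentation_pvalue(counts) < config.theta_pval:
        return True, "underrepresented"
    return False, "known"


class CountProvider(Protocol):
    """Hit-count source: offline table here, a search API in deployment."""

    def count(self, term: str) -> int: ...

    def count_pair(self, a: str, b: str) -> int: ...

    def corpus_size(self) -> int: ...


def _norm(term: str) -> str:
    return " ".join(term.lower().split())


class OfflineCountProvider:
    """CSV/dict-backed count table; unknown terms and pairs count 0."""

    def __init__(
        self,
        term_counts: dict[str, int],
        pair_counts: dict[tuple[str, str], int],
        corpus_size: int = DEFAULT_CORPUS_SIZE,
    ):
        self._terms = {_norm(t): int(c) for t, c in term_counts.items()}
        self._pairs = {
            tuple(sorted((_norm(a), _norm(b)))): int(c)
            for (a, b), c in pair_counts.items()
        }
        self._N = int(corpus_size)

    @classmethod
    def from_csv(
        cls,
        term_file: str | Path,
        pair_file: str | Path,
        corpus_size: int = DEFAULT_CORPUS_SIZE,
    ) -> "OfflineCountProvider":
        terms: dict[str, int] = {}
        with open(term_file, newline="") as fh:
            for row in csv.DictReader(fh):
                terms[row["term"]] = int(row["count"])
        pairs: dict[tuple[str, str], int] = {}
        with open(pair_file, newline="") as fh:
            for row in csv.DictReader(fh):
                pairs[(row["term_a"], row["term_b"])] = int(row["pair_count"])
        return cls(terms, pairs, corpus_size)

    def count(self, term: str) -> int:
        return self._terms.get(_norm(term), 0)

    def count_pair(self, a: str, b: str) -> int:
        return self._pairs.get(tuple(sorted((_norm(a), _norm(b)))), 0)

    def corpus_size(self) -> int:
        return self._N


def counts_for_pair(provider: CountProvider, feature_term: str, target_term: str) -> LiteratureCounts:
    """Assemble validated counts for one feature-target pair."""
    n_x = provider.count(feature_term)
    n_y = provider.count(target_term)
    n_xy = min(provider.count_pair(feature_term, target_term), n_x, n_y)
    return LiteratureCounts(n_x=n_x, n_y=n_y, n_xy=n_xy, N=provider.corpus_size())
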