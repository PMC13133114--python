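"""LLM annotation stage: score surviving candidates for interestingness.

Candidates that pass the utility, knowledge-graph and literature filters
are judged by a language model on three dimensions — novelty, plausibility
and overall interestingness — each on a 1-4 scale with a free-text
rationale.  Prompts use chain-of-thought phrasing and can be augmented
with the top-k BM25-retrieved passages for the feature + target query.
The provider is pluggable: a deterministic scripted provider ships for
offline runs and tests; any completion endpoint can be adapted behind the
same one-method interface.  A second-pass overall scoring by a different
model is just the same annotate step with a different provider handle.

Selection keeps candidates with interestingness > 2, sorted by confidence
(by default the interestingness score itself) with deterministic
tie-breaks, truncated to the top ~30.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from string import Formatter
from typing import Protocol

from pydantic import BaseModel, Field

from ._common import logger

VALID_SCORES = {1, 2, 3, 4}


class LLMConfig(BaseModel):
    provider: str = Field(default="scripted", pattern="^(scripted|openai-compatible)$")
    model: str = "scripted-v1"
    max_retries: int = Field(default=2, ge=0)
    rag_enabled: bool = True
    rag_k: int = Field(default=32, ge=1)
    min_interestingness_exclusive: int = 2
    top_k: int = 30


@dataclass(frozen=True)
class Candidate:
    """A feature-target hypothesis that survived all statistical filters."""

    feature_id: str
    feature_text: str
    target_name: str
    direction: str  # positive | negative
    fimp: float = 0.0
    pval: float = float("nan")
    mi: float = float("nan")


@dataclass
class LLMAnnotation:
    candidate_id: str
    novelty: int
    plausibility: int
    interestingness: int
    confidence: float
    explanations: dict[str, str] = field(default_factory=dict)
    retrieved_context_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("novelty", "plausibility", "interestingness"):
            score = getattr(self, name)
            if score not in VALID_SCORES:
                raise ValueError(f"{name} score {score} outside 1-4")


class LLMProvider(Protocol):
    def complete(self, prompt: str) -> str: ...


class ParseError(ValueError):
    """Raised when a completion lacks a well-formed answer block."""


# ---------------------------------------------------------------- retrieval

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class BM25Index:
    """Okapi BM25 over a small document collection (k1=1.5, b=0.75).

    score(q, d) = sum over query terms of
    idf(t) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * |d| / avgdl)),
    with idf(t) = ln((N - df + 0.5) / (df + 0.5) + 1).
    """

    def __init__(self, docs: list[tuple[str, str]], k1: float = 1.5, b: float = 0.75):
        self.k1, self.b = k1, b
        self.doc_ids = [d[0] for d in docs]
        self._tfs = [
            {t: toks.count(t) for t in set(toks)}
            for toks in (_tokenize(d[1]) for d in docs)
        ]
        self._lens = [sum(tf.values()) for tf in self._tfs]
        self._avgdl = (sum(self._lens) / len(self._lens)) if self._lens else 0.0
        n = len(docs)
        df: dict[str, int] = {}
        for tf in self._tfs:
            for t in tf:
                df[t] = df.get(t, 0) + 1
        self._idf = {t: math.log((n - c + 0.5) / (c + 0.5) + 1.0) for t, c in df.items()}

    def query(self, text: str, k: int) -> list[tuple[str, float]]:
        terms = _tokenize(text)
        scores = []
        for i, tf in enumerate(self._tfs):
            s = 0.0
            for t in terms:
                if t not in tf:
                    continue
                denom = tf[t] + self.k1 * (
                    1 - self.b + self.b * self._lens[i] / self._avgdl
                )
                s += self._idf[t] * tf[t] * (self.k1 + 1) / denom
            scores.append((self.doc_ids[i], s))
        scores.sort(key=lambda r: (-r[1], r[0]))  # stable, deterministic
        return scores[:k]


def retrieve_context(
    candidate: Candidate, index: BM25Index | None, k: int = 32
) -> list[tuple[str, float]]:
    """Top-k BM25 documents for the feature + target query (may be empty)."""
    if index is None or not index.doc_ids:
        return []
    return index.query(f"{candidate.feature_text} {candidate.target_name}", k)


# ------------------------------------------------------------------ prompts

def load_template(name: str = "annotation") -> str:
    """Load a bundled prompt template (config-file text, not code)."""
    return (
        resources.files("featsieve.templates").joinpath(f"{name}_prompt.txt").read_text()
    )


def build_prompt(
    candidate: Candidate,
    context_docs: list[tuple[str, str]] | None,
    template: str,
) -> str:
    """Fill the prompt template; every declared slot must be provided.

    Slots: candidate_id, feature, target, direction, statistics, context.
    The context section collapses to an empty string when no documents
    were retrieved; the prompt remains valid.
    """
    if context_docs:
        ctx_lines = [f"[{doc_id}] {text}" for doc_id, text in context_docs]
        context = "Relevant retrieved passages:\n" + "\n".join(ctx_lines)
    else:
        context = ""
    stats_text = (
        f"association p-value {candidate.pval:.3g}, "
        f"mutual information {candidate.mi:.3g} nats, "
        f"model importance {candidate.fimp:.3g}"
    )
    values = {
        "candidate_id": candidate.feature_id,
        "feature": candidate.feature_text,
        "target": candidate.target_name,
        "direction": candidate.direction,
        "statistics": stats_text,
        "context": context,
    }
    slots = {f for _, f, _, _ in Formatter().parse(template) if f}
    missing = slots - values.keys()
    if missing:
        raise ValueError(f"template slots without values: {sorted(missing)}")
    return template.format(**values)


_SCORE_RES = {
    name: re.compile(rf"^{name.upper()}:\s*(\S+)\s*$", re.MULTILINE)
    for name in ("novelty", "plausibility", "interestingness")
}
_EXPL_RES = {
    name: re.compile(
        rf"^{name.upper()}_EXPLANATION:\s*(.*)$", re.MULTILINE
    )
    for name in ("novelty", "plausibility", "interestingness")
}


def parse_annotation(raw_text: str, candidate_id: str = "?") -> LLMAnnotation:
    """Extract the three 1-4 scores and explanations from a completion.

    The answer block is expected to contain ``NOVELTY: <n>`` /
    ``PLAUSIBILITY: <n>`` / ``INTERESTINGNESS: <n>`` lines with optional
    ``*_EXPLANATION:`` lines.  Missing or ill-typed scores raise
    ParseError; out-of-range scores raise ValueError.
    """
    scores: dict[str, int] = {}
    for name, pattern in _SCORE_RES.items():
        m = pattern.search(raw_text)
        if m is None:
            raise ParseError(f"missing {name.upper()} score in completion")
        try:
            scores[name] = int(m.group(1))
        except ValueError as exc:
            raise ParseError(f"ill-typed {name.upper()} score {m.group(1)!r}") from exc
    explanations = {
        name: m.group(1).strip()
        for name, pattern in _EXPL_RES.items()
        if (m := pattern.search(raw_text)) is not None
    }
    return LLMAnnotation(
        candidate_id=candidate_id,
        novelty=scores["novelty"],
        plausibility=scores["plausibility"],
        interestingness=scores["interestingness"],
        confidence=float(scores["interestingness"]),
        explanations=explanations,
    )


def binarize(score: int) -> bool:
    """Binarize a 1-4 score at > 2 (the model-vs-expert comparison rule)."""
    if score not in VALID_SCORES:
        raise ValueError(f"score {score} outside 1-4")
    return score > 2


# ----------------------------------------------------------- scripted mock

class ScriptedLLMProvider:
    """Deterministic test double: answers from a candidate-id -> scores map.

    The script maps candidate id to (novelty, plausibility,
    interestingness) or a dict that may add explanations.  Unknown
    candidates fall back to ``default`` scores or raise KeyError when no
    default was configured.
    """

    def __init__(
        self,
        script: dict[str, tuple | dict],
        default: tuple[int, int, int] | None = None,
    ):
        self.script = {cid: self._normalize(cid, entry) for cid, entry in script.items()}
        self.default = None
        if default is not None:
            self.default = self._normalize("<default>", tuple(default))

    @staticmethod
    def _normalize(cid: str, entry: tuple | dict) -> dict:
        if isinstance(entry, dict):
            scores = (entry["novelty"], entry["plausibility"], entry["interestingness"])
            expl = entry.get("explanations", {})
        else:
            scores = tuple(entry)
            expl = {}
        for s in scores:
            if s not in VALID_SCORES:
                raise ValueError(f"scripted score {s} for {cid!r} outside 1-4")
        return {
            "novelty": scores[0],
            "plausibility": scores[1],
            "interestingness": scores[2],
            "explanations": expl,
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "ScriptedLLMProvider":
        data = json.loads(Path(path).read_text())
        return cls(data.get("script", {}), default=data.get("default"))

    def complete(self, prompt: str) -> str:
        m = re.search(r"candidate_id:\s*(\S+)", prompt)
        if m is None:
            raise ValueError("prompt carries no candidate_id line")
        cid = m.group(1)
        entry = self.script.get(cid, self.default)
        if entry is None:
            raise KeyError(f"no scripted annotation for candidate {cid!r}")
        lines = []
        for name in ("novelty", "plausibility", "interestingness"):
            lines.append(f"{name.upper()}: {entry[name]}")
            expl = entry["explanations"].get(name, f"scripted rationale for {cid}")
            lines.append(f"{name.upper()}_EXPLANATION: {expl}")
        return "Reasoning: scripted deterministic response.\n" + "\n".join(lines)


class BrokenScriptProvider:
    """Always returns an unparseable completion (error-path testing)."""

    def complete(self, prompt: str) -> str:  # noqa: ARG002
        return "no structured answer block here"


# ---------------------------------------------------------------- annotate

def annotate_candidates(
    candidates: list[Candidate],
    provider: LLMProvider,
    template: str | None = None,
    index: BM25Index | None = None,
    config: LLMConfig | None = None,
    corpus_docs: dict[str, str] | None = None,
) -> tuple[list[LLMAnnotation], list[str]]:
    """Annotate every candidate; returns (annotations, unannotated ids).

    Unparseable completions are retried up to ``max_retries`` times, then
    the candidate is flagged as unannotated and excluded from selection.
    """
    config = config or LLMConfig()
    template = template or load_template()
    annotations: list[LLMAnnotation] = []
    failed: list[str] = []
    for cand in candidates:
        ranked = (
            retrieve_context(cand, index, config.rag_k) if config.rag_enabled else []
        )
        docs = [
            (doc_id, (corpus_docs or {}).get(doc_id, "")) for doc_id, _ in ranked
        ]
        prompt = build_prompt(cand, docs, template)
        annotation = None
        for _attempt in range(config.max_retries + 1):
            try:
                annotation = parse_annotation(provider.complete(prompt), cand.feature_id)
                break
            except ParseError as exc:
                logger.warning("unparseable completion for %s: %s", cand.feature_id, exc)
        if annotation is None:
            failed.append(cand.feature_id)
            continue
        annotation.retrieved_context_ids = [doc_id for doc_id, _ in ranked]
        annotations.append(annotation)
    return annotations, failed


def select_candidates(
    annotations: list[LLMAnnotation],
    fimp_by_id: dict[str, float] | None = None,
    min_interestingness_exclusive: int = 2,
    top_k: int = 30,
) -> list[LLMAnnotation]:
    """Final shortlist: interestingness > threshold, ranked, truncated.

    Sort key: confidence descending, then model importance descending,
    then candidate id ascending (deterministic last resort).
    """
    fimp_by_id = fimp_by_id or {}
    kept = [a for a in annotations if a.interestingness > min_interestingness_exclusive]
    kept.sort(
        key=lambda a: (
            -a.confidence,
            -fimp_by_id.get(a.candidate_id, 0.0),
            a.candidate_id,
        )
    )
    return kept[:top_k]
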