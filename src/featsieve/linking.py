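"""Concept linking: map feature text to knowledge-graph entities.

Features are free-text names/descriptions; the knowledge graph is keyed by
CUI-style entity ids.  A pluggable ``LinkerProvider`` proposes candidate
entities with a confidence score and embeds text for cosine similarity.
Candidates are gated three ways, mirroring a high-precision biomedical
entity-linking setup:

* keep at most ``max_entities`` (3) links with confidence >= 0.88,
* drop entities in excluded high-level categories (regex over
  category/name, e.g. "Qualification", "Unit"),
* drop entities with cosine similarity to the feature text below 0.1, and
  flag survivors with similarity >= theta_sim (0.4) as "strongly linked".

The bundled offline provider links by normalized token overlap against an
entity lexicon and embeds with hashed character 3-gram vectors; it is fully
deterministic, so every downstream verdict is reproducible byte-for-byte.
Production deployments can swap in a trained biomedical linker/embedder
behind the same interface.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol

import numpy as np
from pydantic import BaseModel, Field

from ._common import logger


class LinkConfig(BaseModel):
    max_entities: int = Field(default=3, ge=1)
    min_link_score: float = Field(default=0.88, ge=0.0, le=1.0)
    low_sim: float = 0.1
    theta_sim: float = 0.4
    exclude_patterns: list[str] = Field(
        default_factory=lambda: ["Qualification", "Unit", "Activity"]
    )


@dataclass(frozen=True)
class ConceptLink:
    feature_id: str
    entity_id: str
    entity_name: str
    surface: str
    linker_score: float
    sim: float = float("nan")
    strong: bool = False


class LinkerProvider(Protocol):
    """Adapter seam for an entity linker + text embedder."""

    def link(self, text: str) -> list[tuple[str, str, float]]:
        """Return (entity_id, surface_text, confidence) candidates."""
        ...

    def embed(self, text: str) -> np.ndarray: ...


@dataclass
class EntityLexicon:
    """Entity id -> (name, category) table backing the offline linker."""

    entries: dict[str, tuple[str, str]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "EntityLexicon":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["entity_id"]] = (row["name"], row.get("category", ""))
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["entity_id", "name", "category"])
            for eid, (name, cat) in sorted(self.entries.items()):
                w.writerow([eid, name, cat])

    def name_of(self, entity_id: str) -> str:
        return self.entries.get(entity_id, (entity_id, ""))[0]

    def category_of(self, entity_id: str) -> str:
        return self.entries.get(entity_id, ("", ""))[1]


def _tokens(text: str) -> frozenset[str]:
    return frozenset(re.findall(r"[a-z0-9]+", text.lower()))


class LexiconLinker:
    """Deterministic offline provider: token-overlap linking, hashed embedding.

    Linker confidence is the Jaccard overlap between the normalized token
    sets of the query and the entity name (an exact normalized match scores
    1.0).  Embeddings are L2-normalized hashed character 3-gram count
    vectors, so cosine similarity of identical texts is exactly 1.
    """

    def __init__(self, lexicon: EntityLexicon, embed_dim: int = 256):
        self.lexicon = lexicon
        self.embed_dim = embed_dim

    def link(self, text: str) -> list[tuple[str, str, float]]:
        q = _tokens(text)
        if not q:
            return []
        out = []
        for eid, (name, _cat) in self.lexicon.entries.items():
            t = _tokens(name)
            if not t:
                continue
            overlap = len(q & t)
            if overlap:
                out.append((eid, name, overlap / len(q | t)))
        out.sort(key=lambda r: (-r[2], r[0]))
        return out

    def embed(self, text: str) -> np.ndarray:
        s = f"##{re.sub(r'[^a-z0-9 ]', '', text.lower())}##"
        vec = np.zeros(self.embed_dim)
        for i in range(len(s) - 2):
            vec[hash_trigram(s[i : i + 3]) % self.embed_dim] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def hash_trigram(tri: str) -> int:
    """Stable (non-salted) trigram hash; Python's builtin hash is salted."""
    h = 2166136261
    for ch in tri.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        logger.warning("zero-norm embedding; similarity treated as 0")
        return 0.0
    return float(u @ v / (nu * nv))


def link_feature(
    feature_id: str,
    text: str,
    provider: LinkerProvider,
    max_entities: int = 3,
    min_link_score: float = 0.88,
    lexicon: EntityLexicon | None = None,
) -> list[ConceptLink]:
    """Top confident entity candidates for a feature's text.

    Candidates below ``min_link_score`` are discarded; the rest are sorted
    by confidence descending (ties broken by entity id ascending) and
    truncated to ``max_entities``.  An empty result means the feature
    proceeds through the cascade as "unlinked".
    """
    if not text:
        raise ValueError(f"empty text for feature {feature_id!r}")
    try:
        raw = provider.link(text)
    except Exception as exc:  # surface the feature id with provider failures
        raise RuntimeError(f"linker failed for feature {feature_id!r}") from exc
    kept = [(eid, surface, conf) for eid, surface, conf in raw if conf >= min_link_score]
    kept.sort(key=lambda r: (-r[2], r[0]))
    lex = lexicon or getattr(provider, "lexicon", None)
    return [
        ConceptLink(
            feature_id=feature_id,
            entity_id=eid,
            entity_name=lex.name_of(eid) if lex else surface,
            surface=surface,
            linker_score=conf,
        )
        for eid, surface, conf in kept[:max_entities]
    ]


def exclude_categories(
    links: list[ConceptLink],
    patterns: list[str],
    lexicon: EntityLexicon,
) -> list[ConceptLink]:
    """Remove links whose entity category or name matches any pattern."""
    try:
        compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    except re.error as exc:
        raise ValueError(f"invalid exclusion regex: {exc}") from exc
    out = []
    for link in links:
        cat = lexicon.category_of(link.entity_id)
        if any(p.search(cat) or p.search(link.entity_name) for p in compiled):
            logger.info(
                "exclude %s (%s) by category %r", link.entity_id, link.entity_name, cat
            )
            continue
        out.append(link)
    return out


def similarity_gate(
    links: list[ConceptLink],
    provider: LinkerProvider,
    feature_text: str,
    low_sim: float = 0.1,
    theta_sim: float = 0.4,
) -> list[ConceptLink]:
    """Drop low-similarity links; flag high-similarity ones as strong.

    Similarity is the cosine between the feature text embedding and the
    entity's canonical-name embedding.  Links with sim < ``low_sim`` are
    removed; survivors are flagged strong iff sim >= ``theta_sim``.
    """
    fvec = provider.embed(feature_text)
    out = []
    for link in links:
        sim = cosine(fvec, provider.embed(link.entity_name))
        if sim < low_sim:
            logger.info("drop %s: sim %.3f < %.2f", link.entity_id, sim, low_sim)
            continue
        out.append(replace(link, sim=sim, strong=sim >= theta_sim))
    return out


def link_and_gate(
    feature_id: str,
    text: str,
    provider: LinkerProvider,
    lexicon: EntityLexicon,
    config: LinkConfig | None = None,
) -> list[ConceptLink]:
    """Full linking stage for one feature: link, exclude, similarity-gate."""
    config = config or LinkConfig()
    links = link_feature(
        feature_id, text, provider, config.max_entities, config.min_link_score, lexicon
    )
    links = exclude_categories(links, config.exclude_patterns, lexicon)
    return similarity_gate(links, provider, text, config.low_sim, config.theta_sim)
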