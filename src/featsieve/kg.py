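"""Knowledge-graph novelty filter.

The graph is an undirected adjacency over biomedical entities built from
subject-predicate-object triples: predicate direction and type are ignored,
parallel edges merged, and edges supported by fewer than ``min_citations``
unique citations dropped (low-evidence predications are frequently
extraction noise).  Each edge carries the year its association was first
reported, which supports temporal snapshots: re-running the cascade against
the pre-cutoff graph and asking how many surfaced feature-target adjacencies
only entered the graph after the cutoff measures the pipeline's ability to
surface associations ahead of their documentation.

A feature is "known" (not novel) with respect to a target when

* it has linked entities and *all* of them are 1-hop adjacent to some
  target entity, or
* at least one *strongly linked* entity (similarity >= theta_sim) is
  adjacent to a target entity.

Unlinked features are treated as novel-by-default: the filter aims for
precision in exclusion, not recall of known associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from ._common import logger
from .linking import ConceptLink, EntityLexicon

from .evaluate import wilson_ci

TRIPLE_COLUMNS = ["subject_cui", "predicate", "object_cui", "n_citations", "first_year"]


@dataclass
class KnowledgeGraph:
    graph: nx.Graph
    lexicon: EntityLexicon = field(
        default_factory=lambda: EntityLexicon(entries={})
    )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacent(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_year(self, a: str, b: str) -> int | None:
        data = self.graph.get_edge_data(a, b)
        return None if data is None else data.get("first_year")


@dataclass
class NoveltyVerdict:
    feature_id: str
    known: bool
    reason: str  # all-linked-1hop | strong-link-1hop | not-known | unlinked
    witnesses: list[str] = field(default_factory=list)


def load_kg(
    triple_file: str | Path | pd.DataFrame,
    min_citations: int = 2,
    lexicon: EntityLexicon | None = None,
) -> KnowledgeGraph:
    """Build the evidence-filtered undirected graph from a triple table.

    Parallel/reversed edges are merged first (keeping the maximum evidence
    count and the earliest first-report year), then edges below the
    evidence threshold are dropped.  Self-loops are discarded.  Entities
    appearing in edges but absent from the lexicon are auto-registered
    with an empty category.
    """
    if isinstance(triple_file, pd.DataFrame):
        df = triple_file.copy()
    else:
        df = pd.read_csv(triple_file)
    missing = [c for c in TRIPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"triple file missing columns: {missing}")
    lex = lexicon or EntityLexicon(entries={})
    merged: dict[tuple[str, str], tuple[int, int]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            s, o = str(row.subject_cui), str(row.object_cui)
            cites, year = int(row.n_citations), int(row.first_year)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed triple at line {i + 2}: {exc}") from exc
        if cites < 0:
            raise ValueError(f"negative citation count at line {i + 2}")
        if s == o:
            continue
        key = (s, o) if s <= o else (o, s)
        if key in merged:
            c0, y0 = merged[key]
            merged[key] = (max(c0, cites), min(y0, year))
        else:
            merged[key] = (cites, year)
    graph = nx.Graph()
    for (s, o), (cites, year) in merged.items():
        if cites < min_citations:
            continue
        for node in (s, o):
            if node not in lex.entries:
                logger.warning("unregistered entity %s; empty category", node)
                lex.entries[node] = (node, "")
        graph.add_edge(s, o, evidence_count=cites, first_year=year)
    return KnowledgeGraph(graph=graph, lexicon=lex)


def is_known(
    feature_links: list[ConceptLink],
    target_entities: list[str],
    kg: KnowledgeGraph,
    theta_sim: float = 0.4,
) -> NoveltyVerdict:
    """Apply the 1-hop known-association rule to one feature's links.

    known = (links nonempty AND every linked entity adjacent to >= 1
    target entity) OR (some link with sim >= theta_sim whose entity is
    adjacent to >= 1 target entity).
    """
    if not target_entities:
        raise ValueError("target_entities must be nonempty")
    fid = feature_links[0].feature_id if feature_links else "?"
    if not feature_links:
        return NoveltyVerdict(fid, known=False, reason="unlinked")

    def hits(link: ConceptLink) -> list[str]:
        return [t for t in target_entities if kg.adjacent(link.entity_id, t)]

    adjacency = {link.entity_id: hits(link) for link in feature_links}
    if all(adjacency[l.entity_id] for l in feature_links):
        return NoveltyVerdict(
            fid, known=True, reason="all-linked-1hop",
            witnesses=[l.entity_id for l in feature_links],
        )
    strong_hits = [
        l.entity_id
        for l in feature_links
        if (l.strong or (l.sim == l.sim and l.sim >= theta_sim)) and adjacency[l.entity_id]
    ]
    if strong_hits:
        return NoveltyVerdict(fid, known=True, reason="strong-link-1hop", witnesses=strong_hits)
    return NoveltyVerdict(fid, known=False, reason="not-known")


def temporal_split(kg: KnowledgeGraph, cutoff_year: int) -> tuple[KnowledgeGraph, KnowledgeGraph]:
    """Partition edges into (first_year <= cutoff) and (first_year > cutoff)."""
    pre, post = nx.Graph(), nx.Graph()
    missing = [
        (u, v) for u, v, d in kg.graph.edges(data=True) if d.get("first_year") is None
    ]
    if missing:
        raise ValueError(f"edges missing first_year: {missing[:5]}")
    for u, v, d in kg.graph.edges(data=True):
        (pre if d["first_year"] <= cutoff_year else post).add_edge(u, v, **d)
    return KnowledgeGraph(pre, kg.lexicon), KnowledgeGraph(post, kg.lexicon)


@dataclass
class TemporalSummary:
    """Counts for the time-split reality check of the utility filter."""

    n_kg_linked: int       # utility-passing features with >=1 entity in the KG
    n_one_hop: int         # ... of those, adjacent (1-hop) to the target
    n_post_cutoff: int     # ... of those, earliest adjacency after the cutoff
    pct_post_cutoff: float
    ci_low: float
    ci_high: float

    def as_row(self) -> dict:
        return {
            "kg_linked": self.n_kg_linked,
            "one_hop": self.n_one_hop,
            "post_cutoff": self.n_post_cutoff,
            "pct_post_cutoff": self.pct_post_cutoff,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
        }


def temporal_validation(
    utility_features: list[str],
    feature_links: dict[str, list[ConceptLink]],
    target_entities: list[str],
    kg: KnowledgeGraph,
    cutoff_year: int,
) -> TemporalSummary:
    """Count utility-filtered features whose target link postdates the cutoff.

    For each feature: (i) does any linked entity exist in the full KG,
    (ii) is any linked entity 1-hop from a target entity, (iii) among
    1-hop features, is the *earliest* feature-target edge year after the
    cutoff.  The post-cutoff share uses the 1-hop count as denominator,
    with a 95% Wilson interval.
    """
    n_linked = n_hop = n_post = 0
    for fid in utility_features:
        links = feature_links.get(fid, [])
        in_kg = [l for l in links if l.entity_id in kg.graph]
        if not in_kg:
            continue
        n_linked += 1
        years = [
            kg.edge_year(l.entity_id, t)
            for l in in_kg
            for t in target_entities
            if kg.adjacent(l.entity_id, t)
        ]
        if not years:
            continue
        n_hop += 1
        if min(years) > cutoff_year:
            n_post += 1
    if n_hop == 0:
        return TemporalSummary(n_linked, 0, 0, 0.0, 0.0, 1.0)
    lo, hi = wilson_ci(n_post, n_hop)
    return TemporalSummary(n_linked, n_hop, n_post, 100.0 * n_post / n_hop, lo, hi)
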