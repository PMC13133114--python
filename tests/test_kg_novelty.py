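"""Knowledge-graph loading, the 1-hop known rule, temporal validation."""

import itertools

import pandas as pd
import pytest

import featsieve as fs
from featsieve.kg import TemporalSummary


def triples(rows):
    return pd.DataFrame(
        rows, columns=["subject_cui", "predicate", "object_cui", "n_citations", "first_year"]
    )


def make_link(fid, eid, sim=0.2, strong=None):
    strong = sim >= 0.4 if strong is None else strong
    return fs.ConceptLink(fid, eid, eid, eid, 0.9, sim=sim, strong=strong)


class TestLoadKG:
    def test_single_citation_edge_dropped(self):
        kg = fs.load_kg(triples([("A", "P", "B", 1, 2000)]))
        assert not kg.adjacent("A", "B")

    def test_reversed_parallel_edges_merge_undirected(self):
        kg = fs.load_kg(
            triples([("A", "P1", "B", 2, 2005), ("B", "P2", "A", 4, 2001)])
        )
        assert kg.n_edges == 1
        assert kg.graph["A"]["B"]["evidence_count"] == 4
        assert kg.edge_year("A", "B") == 2001

    def test_edge_count_after_evidence_filter(self):
        rows = [(f"A{i}", "P", f"B{i}", 1 if i < 4 else 3, 2000) for i in range(10)]
        kg = fs.load_kg(triples(rows))
        assert kg.n_edges == 6

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ValueError, match="line 3"):
            fs.load_kg(triples([("A", "P", "B", 2, 2000), ("C", "P", "D", "bad", 2000)]))

    def test_self_loops_discarded(self):
        kg = fs.load_kg(triples([("A", "P", "A", 5, 2000)]))
        assert kg.n_edges == 0


def brute_force_known(links, targets, kg):
    """Independent re-statement of the rule: all-linked-1hop OR strong-1hop."""
    if not links:
        return False
    adjacent = {l.entity_id: any(kg.adjacent(l.entity_id, t) for t in targets) for l in links}
    clause1 = all(adjacent[l.entity_id] for l in links)
    clause2 = any(l.strong and adjacent[l.entity_id] for l in links)
    return clause1 or clause2


class TestIsKnown:
    @pytest.fixture()
    def toy_kg(self):
        return fs.load_kg(
            triples(
                [
                    ("E1", "P", "T", 3, 2000),
                    ("E2", "P", "T", 3, 2000),
                    ("E3", "P", "E4", 3, 2000),  # not target-adjacent
                ]
            )
        )

    def test_all_linked_one_hop(self, toy_kg):
        v = fs.is_known([make_link("f", "E1"), make_link("f", "E2")], ["T"], toy_kg)
        assert v.known and v.reason == "all-linked-1hop"

    def test_single_strong_adjacent_entity_suffices(self, toy_kg):
        links = [make_link("f", "E1", sim=0.9), make_link("f", "E3"), make_link("f", "E4")]
        v = fs.is_known(links, ["T"], toy_kg)
        assert v.known and v.reason == "strong-link-1hop" and v.witnesses == ["E1"]

    def test_weak_partial_adjacency_is_not_known(self, toy_kg):
        v = fs.is_known([make_link("f", "E1"), make_link("f", "E3")], ["T"], toy_kg)
        assert not v.known and v.reason == "not-known"

    def test_unlinked_feature_is_novel_by_default(self, toy_kg):
        v = fs.is_known([], ["T"], toy_kg)
        assert not v.known and v.reason == "unlinked"

    def test_empty_target_set_is_an_error(self, toy_kg):
        with pytest.raises(ValueError, match="target"):
            fs.is_known([make_link("f", "E1")], [], toy_kg)

    def test_rule_matches_brute_force_on_all_link_configurations(self):
        # 6-node graph: E1, E2 adjacent to target T; E3, E4 not; plus N
        kg = fs.load_kg(
            triples([("E1", "P", "T", 3, 2000), ("E2", "P", "T", 3, 2000),
                     ("E3", "P", "N", 3, 2000)])
        )
        entities = ["E1", "E2", "E3", "E4"]
        checked = 0
        for size in range(4):
            for combo in itertools.combinations(entities, size):
                for strongs in itertools.product([False, True], repeat=size):
                    links = [
                        make_link("f", e, sim=0.9 if s else 0.2)
                        for e, s in zip(combo, strongs)
                    ]
                    verdict = fs.is_known(links, ["T"], kg)
                    assert verdict.known == brute_force_known(links, ["T"], kg)
                    checked += 1
        assert checked == 1 + 4 * 2 + 6 * 4 + 4 * 8  # all configurations size <= 3

    def test_adding_edges_never_flips_known_to_novel(self):
        base_rows = [("E1", "P", "T", 3, 2000)]
        extra = ("E3", "P", "T", 3, 2000)
        kg_small = fs.load_kg(triples(base_rows))
        kg_big = fs.load_kg(triples(base_rows + [extra]))
        for size in range(4):
            for combo in itertools.combinations(["E1", "E2", "E3"], size):
                links = [make_link("f", e, sim=0.9) for e in combo]
                if fs.is_known(links, ["T"], kg_small).known:
                    assert fs.is_known(links, ["T"], kg_big).known


class TestTemporalSplit:
    def test_all_pre_cutoff_leaves_post_empty(self):
        kg = fs.load_kg(triples([("A", "P", "B", 3, 2005), ("C", "P", "D", 3, 2005)]))
        pre, post = fs.temporal_split(kg, 2011)
        assert pre.n_edges == 2 and post.n_edges == 0

    def test_post_cutoff_edge_lands_in_post_graph(self):
        kg = fs.load_kg(triples([("A", "P", "B", 3, 2012)]))
        pre, post = fs.temporal_split(kg, 2011)
        assert pre.n_edges == 0 and post.adjacent("A", "B")

    def test_split_partitions_edges(self, small_kg):
        pre, post = fs.temporal_split(small_kg, 2011)
        assert pre.n_edges + post.n_edges == small_kg.n_edges


class TestTemporalValidation:
    @staticmethod
    def synthetic_validation_world(n_linked, n_hop, n_post, cutoff=2011):
        """n_linked features in the KG, n_hop of them target-adjacent,
        n_post of those with a post-cutoff first-report year."""
        rows, links = [], {}
        feats = [f"f{i}" for i in range(n_linked)]
        for i, f in enumerate(feats):
            ent = f"E{i}"
            links[f] = [make_link(f, ent)]
            if i < n_hop:
                year = cutoff + 1 if i < n_post else cutoff - 5
                rows.append((ent, "P", "T", 3, year))
            else:
                rows.append((ent, "P", f"N{i}", 3, 2000))
        return feats, links, fs.load_kg(triples(rows))

    def test_gout_scale_counts_reproduce_published_summary(self):
        feats, links, kg = self.synthetic_validation_world(920, 274, 58)
        s = fs.temporal_validation(feats, links, ["T"], kg, 2011)
        assert (s.n_kg_linked, s.n_one_hop, s.n_post_cutoff) == (920, 274, 58)
        assert round(s.pct_post_cutoff) == 21
        assert (round(100 * s.ci_low), round(100 * s.ci_high)) == (17, 26)

    def test_zero_post_cutoff_with_wilson_interval(self):
        feats, links, kg = self.synthetic_validation_world(40, 10, 0)
        s = fs.temporal_validation(feats, links, ["T"], kg, 2011)
        assert s.pct_post_cutoff == 0.0
        assert (round(100 * s.ci_low), round(100 * s.ci_high)) == (0, 28)

    def test_all_pre_cutoff_counts_zero_post(self):
        feats, links, kg = self.synthetic_validation_world(5, 3, 0)
        s = fs.temporal_validation(feats, links, ["T"], kg, 2011)
        assert s.n_post_cutoff == 0

    def test_denominators_are_nested(self, bundle, small_kg):
        from featsieve.linking import LexiconLinker

        provider = LexiconLinker(bundle.lexicon)
        links = {
            f: fs.link_and_gate(f, bundle.cohort.description_of(f), provider, bundle.lexicon)
            for f in bundle.cohort.feature_cols
        }
        s = fs.temporal_validation(
            bundle.cohort.feature_cols, links, bundle.target_entities, small_kg, 2011
        )
        assert s.n_post_cutoff <= s.n_one_hop <= s.n_kg_linked
        assert isinstance(s, TemporalSummary)
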