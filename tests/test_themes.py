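"""Theme hierarchy, latent topics, prevalence, thresholding, co-mention network."""

from __future__ import annotations

import numpy as np
import pytest

from mdslisten import (ThemeHierarchy, assign_categories, build_theme_network,
                       categorize_theme, fit_latent_topics,
                       merge_latent_into_hierarchy, score_prevalence)
from mdslisten.themes import BROAD_CATEGORIES, ROOT_THEMES


@pytest.fixture(scope="module")
def hierarchy():
    return ThemeHierarchy.default()


class TestHierarchy:
    def test_roots_and_categories_are_canonical(self, hierarchy):
        assert set(hierarchy.roots) == set(ROOT_THEMES)
        assert set(hierarchy.categories) == set(BROAD_CATEGORIES)

    def test_every_subtheme_reaches_a_root(self, hierarchy):
        for node in hierarchy.nodes:
            roots = hierarchy.roots_of(node)
            assert roots and all(r in ROOT_THEMES for r in roots)

    def test_subtheme_with_unknown_root_rejected(self, hierarchy):
        h = hierarchy.copy()
        with pytest.raises(ValueError):
            h.add_subtheme("x", ["not a root"], ["seed"])


class TestAssign:
    def test_transplant_post_hits_transplants_category(self, hierarchy):
        a = assign_categories("worried about bone marrow transplant risks", hierarchy)
        assert "transplants" in a.categories

    def test_empty_text_gets_empty_assignment(self, hierarchy):
        a = assign_categories("", hierarchy)
        assert not a.categories and not a.themes

    def test_multilabel_when_two_categories_match(self, hierarchy):
        a = assign_categories("fatigue after the transfusion", hierarchy)
        assert {"physical", "treatments"} <= a.category_set

    def test_score_is_matched_seed_fraction(self, hierarchy):
        a = assign_categories("fatigue and pain and nausea", hierarchy)
        n_seeds = len(hierarchy.categories["physical"])
        assert a.categories["physical"] == pytest.approx(3 / n_seeds)

    def test_planted_themes_recovered_on_synthetic_posts(self, small_corpus, hierarchy):
        corpus, gt = small_corpus
        for p in corpus.posts[:300]:
            a = assign_categories(p, hierarchy)
            assert gt.post_themes[p.post_id] <= a.theme_set, p.post_id


@pytest.fixture(scope="module")
def planted_texts():
    rng = np.random.default_rng(0)
    vocab = {
        0: ["apple", "orchard", "cider", "harvest", "pie"],
        1: ["engine", "piston", "gearbox", "torque", "diesel"],
        2: ["sonata", "violin", "tempo", "quartet", "aria"],
    }
    texts, labels = [], []
    for label, words in vocab.items():
        for _ in range(30):
            picks = rng.choice(words, size=6)
            texts.append(" ".join(picks))
            labels.append(label)
    return texts, np.array(labels)


class TestLatentTopics:
    def test_k1_puts_everything_in_one_topic(self):
        model = fit_latent_topics(["apple orchard", "orchard cider", "cider apple"],
                                  method="kmeans", k=1, min_df=1)
        assert set(model.assignments.tolist()) == {0}

    @pytest.mark.parametrize("method", ["kmeans", "lda", "lsa", "agglomerative"])
    def test_purity_on_disjoint_vocabularies(self, planted_texts, method):
        texts, labels = planted_texts
        model = fit_latent_topics(texts, method=method, k=3, seed=0, min_df=2)
        purity = 0
        for topic in set(model.assignments.tolist()):
            members = labels[model.assignments == topic]
            purity += np.bincount(members).max()
        assert purity / len(labels) >= 0.9

    def test_fixed_seed_reproduces_assignments(self, planted_texts):
        texts, _ = planted_texts
        m1 = fit_latent_topics(texts, method="lda", k=3, seed=4)
        m2 = fit_latent_topics(texts, method="lda", k=3, seed=4)
        assert np.array_equal(m1.assignments, m2.assignments)
        assert m1.topic_terms == m2.topic_terms

    def test_k_exceeding_corpus_is_fatal(self):
        with pytest.raises(ValueError):
            fit_latent_topics(["one text", "two text"], method="kmeans", k=5)

    def test_density_methods_may_emit_noise(self, planted_texts):
        texts, _ = planted_texts
        model = fit_latent_topics(texts, method="dbscan", k=None, min_df=2)
        assert set(model.assignments.tolist()) <= set(range(-1, len(texts)))


class TestMerge:
    def _model(self):
        return fit_latent_topics(
            ["insurance paperwork referral", "insurance referral paperwork",
             "hugs support encouragement", "support hugs encouragement"],
            method="kmeans", k=2, seed=0, min_df=1)

    def test_map_attaches_terms_to_existing_node(self, hierarchy):
        model = self._model()
        mapping = {tid: ("map", "unmet needs") for tid in model.topic_ids}
        merged = merge_latent_into_hierarchy(model, hierarchy, mapping)
        seeds = set(merged.seeds_of("unmet needs"))
        for tid in model.topic_ids:
            assert set(model.topic_terms[tid]) <= seeds
        assert set(hierarchy.nodes) <= set(merged.nodes)  # nothing removed

    def test_new_subtheme_created_with_topic_terms(self, hierarchy):
        model = self._model()
        mapping = {model.topic_ids[0]: ("new", "paperwork burden", ["logistic burden"]),
                   model.topic_ids[1]: ("discard",)}
        merged = merge_latent_into_hierarchy(model, hierarchy, mapping)
        assert "paperwork burden" in merged.nodes
        assert merged.roots_of("paperwork burden") == ("logistic burden",)

    def test_discarded_topic_leaves_hierarchy_unchanged(self, hierarchy):
        model = self._model()
        mapping = {tid: ("discard",) for tid in model.topic_ids}
        merged = merge_latent_into_hierarchy(model, hierarchy, mapping)
        assert set(merged.nodes) == set(hierarchy.nodes)

    def test_incomplete_or_bad_mapping_fatal(self, hierarchy):
        model = self._model()
        with pytest.raises(ValueError):
            merge_latent_into_hierarchy(model, hierarchy, {})
        with pytest.raises(ValueError):
            merge_latent_into_hierarchy(
                model, hierarchy, {tid: ("map", "nope") for tid in model.topic_ids})


def _brute_force_prevalence(assignments, discussion_of):
    themes = {t for labels in assignments.values() for t in labels}
    out = {}
    for theme in themes:
        discs = {discussion_of[pid] for pid, labels in assignments.items()
                 if theme in labels}
        out[theme] = len(discs)
    return out


def _brute_force_weight(assignments, discussion_of, a, b):
    count = 0
    for disc in set(discussion_of.values()):
        in_disc = [pid for pid, d in discussion_of.items() if d == disc]
        labels = set().union(*(assignments[pid] for pid in in_disc))
        if a in labels and b in labels:
            count += 1
    return count


@pytest.fixture(scope="module")
def random_assignment():
    rng = np.random.default_rng(12)
    themes = [f"theme{i}" for i in range(8)]
    assignments, discussion_of = {}, {}
    for pid in range(200):
        discussion_of[f"p{pid}"] = f"d{rng.integers(40)}"  # <=50 discussions
        k = rng.integers(0, 4)
        assignments[f"p{pid}"] = set(rng.choice(themes, size=k, replace=False))
    return assignments, discussion_of


class TestPrevalence:
    def test_multiple_posts_in_one_thread_count_once(self):
        assignments = {"p1": {"A"}, "p2": {"A"}, "p3": {"A"}}
        discussion_of = {"p1": "d1", "p2": "d1", "p3": "d1"}
        assert score_prevalence(assignments, discussion_of) == {"A": 1}

    def test_absent_theme_scores_zero(self):
        assert score_prevalence({"p1": set()}, {"p1": "d1"}) == {}

    def test_two_threads_count_two(self):
        assignments = {"p1": {"A"}, "p2": {"A"}}
        discussion_of = {"p1": "d1", "p2": "d2"}
        assert score_prevalence(assignments, discussion_of)["A"] == 2

    def test_equals_brute_force_oracle(self, random_assignment):
        assignments, discussion_of = random_assignment
        assert score_prevalence(assignments, discussion_of) == \
            _brute_force_prevalence(assignments, discussion_of)

    def test_prevalence_bounded_by_discussions(self, random_assignment):
        assignments, discussion_of = random_assignment
        n_disc = len(set(discussion_of.values()))
        for v in score_prevalence(assignments, discussion_of).values():
            assert v <= n_disc


class TestCategorize:
    @pytest.mark.parametrize("prevalence,threshold,size", [
        (10, 10, "major"),  # inclusive boundary
        (9, 10, "minor"),
        (0, 1, "minor"),
    ])
    def test_threshold(self, prevalence, threshold, size):
        assert categorize_theme("t", prevalence, threshold, True)[0] == size

    def test_emotional_support_is_nonactionable(self, hierarchy):
        assert not hierarchy.is_actionable("emotional support")
        _, act = categorize_theme("emotional support", 100, 1,
                                  hierarchy.is_actionable("emotional support"))
        assert act == "nonactionable"


class TestNetwork:
    def test_pair_in_single_shared_thread_weight_one(self):
        g = build_theme_network({"p1": {"A"}, "p2": {"B"}},
                                {"p1": "d1", "p2": "d1"})
        assert g["A"]["B"]["weight"] == 1

    def test_theme_without_co_mention_is_isolated(self):
        g = build_theme_network({"p1": {"A", "B"}, "p2": {"C"}},
                                {"p1": "d1", "p2": "d2"})
        assert "C" in g.nodes and g.degree("C") == 0

    def test_no_self_loops_and_positive_integer_weights(self, random_assignment):
        assignments, discussion_of = random_assignment
        g = build_theme_network(assignments, discussion_of)
        assert not list(__import__("networkx").selfloop_edges(g))
        for _, _, d in g.edges(data=True):
            assert isinstance(d["weight"], int) and d["weight"] > 0

    def test_weights_equal_brute_force_oracle(self, random_assignment):
        assignments, discussion_of = random_assignment
        g = build_theme_network(assignments, discussion_of)
        for a, b, d in g.edges(data=True):
            assert d["weight"] == _brute_force_weight(assignments, discussion_of, a, b)

    def test_weight_bounded_by_min_prevalence(self, random_assignment):
        assignments, discussion_of = random_assignment
        g = build_theme_network(assignments, discussion_of)
        prev = score_prevalence(assignments, discussion_of)
        for a, b, d in g.edges(data=True):
            assert d["weight"] <= min(prev[a], prev[b])
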