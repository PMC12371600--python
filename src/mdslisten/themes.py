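"""Theme hierarchy, top-down category assignment, bottom-up latent topics,
prevalence scoring, major/minor thresholding, and the co-mention network.

"Discussion" means thread throughout: a theme's prevalence is the number of
unique discussions containing at least one post assigned that theme, and two
themes are connected in the network with weight equal to the number of
discussions co-mentioning both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import resources
from .corpus import Corpus, Post

__all__ = [
    "ROOT_THEMES",
    "BROAD_CATEGORIES",
    "ThemeHierarchy",
    "ThemeAssignment",
    "LatentTopicModel",
    "assign_categories",
    "assign_corpus_themes",
    "fit_latent_topics",
    "merge_latent_into_hierarchy",
    "score_prevalence",
    "categorize_theme",
    "build_theme_network",
]

ROOT_THEMES = ("disease burden", "treatment decision", "unmet needs",
               "life milestones", "logistic burden")
BROAD_CATEGORIES = ("clinical", "diet and lifestyle", "education and logistics",
                    "emotional", "physical", "transplants", "treatments")


def _seed_regex(seed: str) -> re.Pattern:
    pattern = re.escape(seed).replace(r"\ ", r"\s+")
    return re.compile(rf"\b{pattern}\b", re.IGNORECASE)


@dataclass
class _Node:
    seeds: list[str]
    actionable: bool
    roots: tuple[str, ...] = ()  # empty for root nodes


class ThemeHierarchy:
    """Five root themes with subtheme branches, plus the seven broad
    categories kept as a parallel label system.

    Every subtheme maps to at least one root; node names are unique across
    roots and subthemes.  Each node carries keyword seeds (for the reference
    top-down classifier) and an actionability flag.
    """

    def __init__(
        self,
        roots: Mapping[str, Mapping],
        subthemes: Mapping[str, Mapping],
        categories: Mapping[str, Sequence[str]],
    ):
        if set(roots) != set(ROOT_THEMES):
            raise ValueError(f"root themes must be exactly {ROOT_THEMES}")
        if set(categories) != set(BROAD_CATEGORIES):
            raise ValueError(f"broad categories must be exactly {BROAD_CATEGORIES}")
        self._nodes: dict[str, _Node] = {}
        for name, spec in roots.items():
            self._nodes[name] = _Node(list(spec["seeds"]), bool(spec["actionable"]))
        for name, spec in subthemes.items():
            self.add_subtheme(name, spec["roots"], spec["seeds"],
                              bool(spec.get("actionable", True)))
        self.categories = {c: list(categories[c]) for c in BROAD_CATEGORIES}
        self._cat_regexes = {
            c: [_seed_regex(s) for s in seeds] for c, seeds in self.categories.items()
        }

    def add_subtheme(self, name: str, roots: Sequence[str], seeds: Sequence[str],
                     actionable: bool = True) -> None:
        if name in self._nodes:
            raise ValueError(f"node {name!r} already exists")
        roots = tuple(roots)
        unknown = [r for r in roots if r not in ROOT_THEMES]
        if unknown or not roots:
            raise ValueError(f"subtheme {name!r} must map to >=1 known root, got {roots}")
        self._nodes[name] = _Node(list(seeds), actionable, roots)
        self._node_regexes = None  # invalidate cache

    _node_regexes: dict | None = None

    def _regexes(self) -> dict[str, list[re.Pattern]]:
        if self._node_regexes is None:
            self._node_regexes = {
                n: [_seed_regex(s) for s in node.seeds] for n, node in self._nodes.items()
            }
        return self._node_regexes

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def roots(self) -> tuple[str, ...]:
        return ROOT_THEMES

    def seeds_of(self, node: str) -> list[str]:
        return list(self._nodes[node].seeds)

    def roots_of(self, node: str) -> tuple[str, ...]:
        n = self._nodes[node]
        return (node,) if not n.roots else n.roots

    def is_actionable(self, node: str) -> bool:
        return self._nodes[node].actionable

    def add_seeds(self, node: str, seeds: Iterable[str]) -> None:
        existing = self._nodes[node].seeds
        for s in seeds:
            if s not in existing:
                existing.append(s)
        self._node_regexes = None

    def copy(self) -> "ThemeHierarchy":
        roots = {n: {"seeds": list(v.seeds), "actionable": v.actionable}
                 for n, v in self._nodes.items() if not v.roots}
        subs = {n: {"roots": list(v.roots), "seeds": list(v.seeds),
                    "actionable": v.actionable}
                for n, v in self._nodes.items() if v.roots}
        return ThemeHierarchy(roots, subs, self.categories)

    @classmethod
    def default(cls) -> "ThemeHierarchy":
        cfg = resources.load_theme_hierarchy_config()
        return cls(cfg["roots"], cfg["subthemes"], cfg["categories"])


@dataclass
class ThemeAssignment:
    post_id: str
    categories: dict[str, float] = field(default_factory=dict)
    themes: dict[str, float] = field(default_factory=dict)

    @property
    def category_set(self) -> frozenset[str]:
        return frozenset(self.categories)

    @property
    def theme_set(self) -> frozenset[str]:
        return frozenset(self.themes)


ThemeModel = Callable[[str], tuple[Mapping[str, float], Mapping[str, float]]]


def assign_categories(
    post: Post | str,
    hierarchy: ThemeHierarchy,
    model: ThemeModel | None = None,
) -> ThemeAssignment:
    """Multilabel category and theme assignment for one post.

    The reference implementation is seeded-keyword scoring: a label is
    assigned when any of its seeds matches, with score = fraction of its
    seeds matched.  A pluggable supervised classifier may replace it.
    """
    text = post.text if isinstance(post, Post) else post
    post_id = post.post_id if isinstance(post, Post) else ""
    if model is not None:
        cats, themes = model(text)
        return ThemeAssignment(post_id, dict(cats), dict(themes))

    categories: dict[str, float] = {}
    for cat, regexes in hierarchy._cat_regexes.items():
        hits = sum(1 for rx in regexes if rx.search(text))
        if hits:
            categories[cat] = hits / len(regexes)
    themes: dict[str, float] = {}
    for node, regexes in hierarchy._regexes().items():
        hits = sum(1 for rx in regexes if rx.search(text))
        if hits:
            themes[node] = hits / len(regexes)
    return ThemeAssignment(post_id, categories, themes)


def assign_corpus_themes(
    corpus: Corpus,
    hierarchy: ThemeHierarchy | None = None,
    model: ThemeModel | None = None,
) -> dict[str, ThemeAssignment]:
    hierarchy = hierarchy or ThemeHierarchy.default()
    return {p.post_id: assign_categories(p, hierarchy, model) for p in corpus.posts}


# ---------------------------------------------------------------------------
# Bottom-up latent topics
# ---------------------------------------------------------------------------

LATENT_METHODS = ("lda", "lsa", "kmeans", "spectral", "agglomerative", "dbscan", "optics")


@dataclass
class LatentTopicModel:
    method: str
    k: int | None
    topic_terms: dict[int, list[str]]
    assignments: np.ndarray  # per-post topic id; -1 = noise (density methods)
    seed: int

    @property
    def topic_ids(self) -> list[int]:
        return sorted(self.topic_terms)


def fit_latent_topics(
    texts: Sequence[str],
    method: str = "lda",
    k: int | None = 10,
    seed: int = 0,
    vectorizer: str = "tfidf",
    min_df: int = 2,
    top_m: int = 10,
    **method_kwargs,
) -> LatentTopicModel:
    """Fit a topic model or document clustering over raw texts.

    Partitional methods (lda, lsa, kmeans, spectral, agglomerative) require
    ``k`` and at least ``k`` documents; density methods (dbscan, optics) may
    label documents as noise (-1).  Deterministic for a fixed seed.
    """
    from sklearn.cluster import (DBSCAN, OPTICS, AgglomerativeClustering,
                                 KMeans, SpectralClustering)
    from sklearn.decomposition import LatentDirichletAllocation, TruncatedSVD
    from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer

    if method not in LATENT_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {LATENT_METHODS}")
    partitional = method in ("lda", "lsa", "kmeans", "spectral", "agglomerative")
    if partitional:
        if k is None or k < 1:
            raise ValueError("k must be >= 1 for partitional methods")
        if k > len(texts):
            raise ValueError(f"k={k} exceeds corpus size {len(texts)}")

    vec_cls = CountVectorizer if (method == "lda" or vectorizer == "tf") else TfidfVectorizer
    vec = vec_cls(lowercase=True, stop_words="english",
                  min_df=min(min_df, max(1, len(texts))))
    X = vec.fit_transform(texts)
    terms = np.asarray(vec.get_feature_names_out())

    def top_terms_from_rows(rows: np.ndarray) -> dict[int, list[str]]:
        out = {}
        for i, row in enumerate(rows):
            idx = np.argsort(row)[::-1][:top_m]
            out[i] = [str(terms[j]) for j in idx if row[j] > 0]
        return out

    def top_terms_from_clusters(labels: np.ndarray) -> dict[int, list[str]]:
        out = {}
        dense = np.asarray(X.todense())
        for lab in sorted(set(int(l) for l in labels)):
            if lab == -1:
                continue
            mean = dense[labels == lab].mean(axis=0)
            idx = np.argsort(mean)[::-1][:top_m]
            out[lab] = [str(terms[j]) for j in idx if mean[j] > 0]
        return out

    if method == "lda":
        model = LatentDirichletAllocation(n_components=k, random_state=seed,
                                          **method_kwargs)
        doc_topic = model.fit_transform(X)
        labels = doc_topic.argmax(axis=1)
        topic_terms = top_terms_from_rows(model.components_)
    elif method == "lsa":
        n_comp = min(k, X.shape[1] - 1) if X.shape[1] > 1 else 1
        model = TruncatedSVD(n_components=max(1, n_comp), random_state=seed,
                             **method_kwargs)
        doc_topic = model.fit_transform(X)
        labels = np.abs(doc_topic).argmax(axis=1)
        topic_terms = top_terms_from_rows(np.abs(model.components_))
    elif method == "kmeans":
        model = KMeans(n_clusters=k, random_state=seed, n_init=10, **method_kwargs)
        labels = model.fit_predict(X)
        topic_terms = top_terms_from_clusters(labels)
    elif method == "spectral":
        model = SpectralClustering(n_clusters=k, random_state=seed,
                                   assign_labels="kmeans", **method_kwargs)
        labels = model.fit_predict(np.asarray(X.todense()))
        topic_terms = top_terms_from_clusters(labels)
    elif method == "agglomerative":
        model = AgglomerativeClustering(n_clusters=k, **method_kwargs)
        labels = model.fit_predict(np.asarray(X.todense()))
        topic_terms = top_terms_from_clusters(labels)
    elif method == "dbscan":
        model = DBSCAN(metric="cosine", **({"eps": 0.6, "min_samples": 3} | method_kwargs))
        labels = model.fit_predict(X)
        topic_terms = top_terms_from_clusters(labels)
    else:  # optics
        model = OPTICS(metric="cosine", **({"min_samples": 3} | method_kwargs))
        labels = model.fit_predict(np.asarray(X.todense()))
        topic_terms = top_terms_from_clusters(labels)

    return LatentTopicModel(method=method, k=k if partitional else None,
                            topic_terms=topic_terms,
                            assignments=np.asarray(labels, dtype=int), seed=seed)


def merge_latent_into_hierarchy(
    model: LatentTopicModel,
    hierarchy: ThemeHierarchy,
    mapping: Mapping[int, tuple],
) -> ThemeHierarchy:
    """Fold reviewed latent topics into the hierarchy.

    ``mapping`` must cover every topic id with a directive: ``("map", node)``
    attaches the topic's top terms as extra seeds of an existing node,
    ``("new", name, roots)`` creates a subtheme seeded with the top terms,
    and ``("discard",)`` drops the topic.  Existing nodes are never removed.
    """
    missing = set(model.topic_ids) - set(mapping)
    if missing:
        raise ValueError(f"mapping does not cover topics {sorted(missing)}")
    out = hierarchy.copy()
    for topic_id in model.topic_ids:
        directive = mapping[topic_id]
        action = directive[0]
        if action == "discard":
            continue
        if action == "map":
            node = directive[1]
            if node not in out.nodes:
                raise ValueError(f"mapping references unknown node {node!r}")
            out.add_seeds(node, model.topic_terms[topic_id])
        elif action == "new":
            name, roots = directive[1], directive[2]
            out.add_subtheme(name, roots, model.topic_terms[topic_id])
        else:
            raise ValueError(f"unknown mapping action {action!r}")
    return out


# ---------------------------------------------------------------------------
# Prevalence, thresholding, network
# ---------------------------------------------------------------------------

def score_prevalence(
    assignments: Mapping[str, Iterable[str]],
    discussion_of: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> dict[str, int]:
    """Theme -> number of unique discussions mentioning it.

    ``assignments`` maps post id to its theme labels, ``discussion_of`` maps
    post id to its thread.  Posts with weight 0 (superuser capping) do not
    contribute.
    """
    discussions: dict[str, set[str]] = {}
    for post_id, labels in assignments.items():
        if weights is not None and weights.get(post_id, 1.0) <= 0:
            continue
        disc = discussion_of[post_id]
        for label in labels:
            discussions.setdefault(label, set()).add(disc)
    return {theme: len(d) for theme, d in discussions.items()}


def categorize_theme(
    theme: str,
    prevalence: int,
    threshold: float,
    actionable: bool,
) -> tuple[str, str]:
    """(major|minor, actionable|nonactionable); major iff prevalence >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    size = "major" if prevalence >= threshold else "minor"
    return size, ("actionable" if actionable else "nonactionable")


def build_theme_network(
    assignments: Mapping[str, Iterable[str]],
    discussion_of: Mapping[str, str],
    weights: Mapping[str, float] | None = None,
) -> nx.Graph:
    """Weighted co-mention network over discussions.

    Edge (a, b) has weight = number of discussions in which both a and b are
    mentioned; zero-weight pairs are absent and there are no self-loops.
    Every mentioned theme is present as a node even if isolated.
    """
    themes_in_disc: dict[str, set[str]] = {}
    all_themes: set[str] = set()
    for post_id, labels in assignments.items():
        if weights is not None and weights.get(post_id, 1.0) <= 0:
            continue
        disc = discussion_of[post_id]
        labels = set(labels)
        all_themes |= labels
        themes_in_disc.setdefault(disc, set()).update(labels)

    graph = nx.Graph()
    graph.add_nodes_from(sorted(all_themes))
    for themes in themes_in_disc.values():
        ordered = sorted(themes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                if graph.has_edge(a, b):
                    graph[a][b]["weight"] += 1
                else:
                    graph.add_edge(a, b, weight=1)
    return graph
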