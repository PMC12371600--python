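"""Patient-vs-caregiver classification.

Each post is first labeled by key-phrase matching ("I have MDS", "my husband
was diagnosed with MDS", ...); a user is then assigned the role carried by at
least 80% of their labeled posts, falling back to a chronological scan for
the first confidently-labeled post when no 80% majority exists.  Phrase
matches carry confidence 1.0; a pluggable classifier (any callable
``text -> (label, confidence)``) may supply labels for phrase-free posts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import resources
from .corpus import Corpus, Post

__all__ = [
    "RolePhraseLexicon",
    "PostRoleLabel",
    "UserRoleDecision",
    "label_post_role",
    "classify_user",
    "classify_corpus_roles",
    "TermFrequencyRoleClassifier",
]

# "MDS" in any phrase also matches the spelled-out disease name
_DISEASE_ALT = r"(?:MDS|myelodysplastic\s+syndromes?)"


def _phrase_to_regex(phrase: str, kin_nouns: Sequence[str] | None = None) -> re.Pattern:
    pattern = re.escape(phrase)
    pattern = pattern.replace(re.escape("MDS"), _DISEASE_ALT)
    if kin_nouns:
        kin_alt = "(?:" + "|".join(re.escape(k) for k in kin_nouns) + ")"
        pattern = pattern.replace(re.escape("{kin}"), kin_alt)
    pattern = pattern.replace(r"\ ", r"\s+")
    return re.compile(rf"\b{pattern}\b", re.IGNORECASE)


class RolePhraseLexicon:
    """Key phrases identifying the author as patient or caregiver.

    Matching is case-insensitive whole-phrase; caregiver patterns are
    third-person kin-noun templates ("my {kin} was diagnosed with MDS").
    Patient and caregiver phrase sets must be disjoint.
    """

    def __init__(self, patient_phrases: Sequence[str],
                 caregiver_patterns: Sequence[str],
                 kin_nouns: Sequence[str]):
        if set(p.lower() for p in patient_phrases) & set(
            c.lower() for c in caregiver_patterns
        ):
            raise ValueError("patient and caregiver phrase sets must be disjoint")
        self.patient_phrases = list(patient_phrases)
        self.caregiver_patterns = list(caregiver_patterns)
        self.kin_nouns = list(kin_nouns)
        self._patient_res = [(p, _phrase_to_regex(p)) for p in patient_phrases]
        self._caregiver_res = [
            (c, _phrase_to_regex(c, kin_nouns)) for c in caregiver_patterns
        ]

    @classmethod
    def default(cls) -> "RolePhraseLexicon":
        cfg = resources.load_role_phrases()
        return cls(cfg["patient"], cfg["caregiver_patterns"], cfg["kin_nouns"])


@dataclass(frozen=True)
class PostRoleLabel:
    post_id: str
    label: str  # patient | caregiver | none
    confidence: float
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class UserRoleDecision:
    user_ref: str
    role: str  # patient | caregiver | unknown
    rule_used: str  # majority_80 | chronological | none
    majority_share: float


RoleFallback = Callable[[str], tuple[str, float]]


def label_post_role(
    post: Post | str,
    lexicon: RolePhraseLexicon,
    fallback: RoleFallback | None = None,
) -> PostRoleLabel:
    """Label one post as patient/caregiver/none.

    A phrase match wins with confidence 1.0; if both phrase sets match, the
    earlier match position decides.  With no match, the fallback classifier
    (if any) is consulted; otherwise the label is ``none``.
    """
    text = post.text if isinstance(post, Post) else post
    post_id = post.post_id if isinstance(post, Post) else ""

    def earliest(regexes) -> tuple[int, str] | None:
        best: tuple[int, str] | None = None
        for phrase, rx in regexes:
            m = rx.search(text)
            if m and (best is None or m.start() < best[0]):
                best = (m.start(), phrase)
        return best

    pat = earliest(lexicon._patient_res)
    care = earliest(lexicon._caregiver_res)
    if pat and care:
        label, evidence = ("patient", pat[1]) if pat[0] <= care[0] else ("caregiver", care[1])
        return PostRoleLabel(post_id, label, 1.0, (evidence,))
    if pat:
        return PostRoleLabel(post_id, "patient", 1.0, (pat[1],))
    if care:
        return PostRoleLabel(post_id, "caregiver", 1.0, (care[1],))
    if fallback is not None:
        label, conf = fallback(text)
        if label in ("patient", "caregiver"):
            return PostRoleLabel(post_id, label, float(conf), ("fallback",))
    return PostRoleLabel(post_id, "none", 0.0)


def classify_user(
    labels: Sequence[PostRoleLabel],
    majority_threshold: float = 0.8,
    confidence_threshold: float = 0.9,
    user_ref: str = "",
) -> UserRoleDecision:
    """Aggregate chronologically-ordered post labels into one user role.

    Posts labeled ``none`` are excluded from the majority denominator (they
    carry no role evidence).  A role covering >= 80% of labeled posts wins
    (boundary inclusive); otherwise the posts are scanned in chronological
    order and the first label with confidence >= ``confidence_threshold``
    is taken.  If nothing qualifies the user stays unknown.
    """
    labeled = [l for l in labels if l.label in ("patient", "caregiver")]
    if labeled:
        n = len(labeled)
        for role in ("patient", "caregiver"):
            share = sum(1 for l in labeled if l.label == role) / n
            if share >= majority_threshold:
                return UserRoleDecision(user_ref, role, "majority_80", share)
        for l in labeled:  # chronological fallback
            if l.confidence >= confidence_threshold:
                share = sum(1 for x in labeled if x.label == l.label) / n
                return UserRoleDecision(user_ref, l.label, "chronological", share)
    return UserRoleDecision(user_ref, "unknown", "none", 0.0)


def classify_corpus_roles(
    corpus: Corpus,
    lexicon: RolePhraseLexicon | None = None,
    fallback: RoleFallback | None = None,
    majority_threshold: float = 0.8,
    confidence_threshold: float = 0.9,
) -> tuple[dict[str, UserRoleDecision], dict[str, PostRoleLabel]]:
    """Label every post, then decide every user; updates ``corpus.users``."""
    lexicon = lexicon or RolePhraseLexicon.default()
    post_labels = {p.post_id: label_post_role(p, lexicon, fallback) for p in corpus.posts}
    decisions: dict[str, UserRoleDecision] = {}
    for user_ref, posts in corpus.posts_by_user().items():
        ordered = sorted(posts, key=lambda p: (p.timestamp, p.post_id))
        labels = [post_labels[p.post_id] for p in ordered]
        decision = classify_user(labels, majority_threshold, confidence_threshold,
                                 user_ref=user_ref)
        decisions[user_ref] = decision
        if user_ref in corpus.users:
            corpus.users[user_ref].role = decision.role
    return decisions, post_labels


class TermFrequencyRoleClassifier:
    """Reference fallback classifier: term-frequency vectors + linear model.

    Trained on labeled example texts (synthetic corpora in this package);
    implements the pluggable ``text -> (label, confidence)`` interface used
    by :func:`label_post_role` for phrase-free posts.
    """

    def __init__(self):
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.linear_model import LogisticRegression

        self._vectorizer = CountVectorizer(lowercase=True)
        self._model = LogisticRegression(max_iter=1000)
        self._fitted = False

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> "TermFrequencyRoleClassifier":
        X = self._vectorizer.fit_transform(texts)
        self._model.fit(X, list(labels))
        self._fitted = True
        return self

    def __call__(self, text: str) -> tuple[str, float]:
        if not self._fitted:
            return "none", 0.0
        X = self._vectorizer.transform([text])
        proba = self._model.predict_proba(X)[0]
        i = int(np.argmax(proba))
        return str(self._model.classes_[i]), float(proba[i])
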