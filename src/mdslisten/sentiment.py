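"""Multilabel emotion classification and cohort-stratified prevalence.

The seven-way emotion scheme (neutral, sadness, joy, surprise, fear, disgust,
anger) is scored per post; the high-risk sub-sentiment buckets (concern,
anxiety, frustration, fear, confusion, plus information seeking) are scored
from the same mechanism and attributed to the themes of the post.

The default scorer is a transparent cue lexicon; the interface accepts any
model returning per-class scores, so a supervised classifier can be plugged
in without touching the aggregation code.  User-level labels are the union
of post-level labels: a user expresses a sentiment if at least one of their
posts does, and prevalence percentages are user-denominated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Collection, Iterable, Mapping, Sequence

import pandas as pd

from . import resources
from .corpus import Corpus, Post

__all__ = [
    "EMOTION_CLASSES",
    "HR_BUCKETS",
    "EmotionLabelSet",
    "CueLexiconScorer",
    "SubSentimentMap",
    "classify_emotions",
    "classify_buckets",
    "map_subsentiments",
    "PrevalenceRow",
    "PrevalenceTable",
    "aggregate_prevalence",
    "round_half_away",
    "percentage",
    "user_label_union",
]

EMOTION_CLASSES = ("neutral", "sadness", "joy", "surprise", "fear", "disgust", "anger")
FINER_LABELS = ("worry", "hopefulness")
HR_BUCKETS = ("concern", "anxiety", "frustration", "fear", "confusion",
              "information_seeking")


def _cue_regex(cue: str) -> re.Pattern:
    pattern = re.escape(cue).replace(r"\ ", r"\s+")
    return re.compile(rf"\b{pattern}\b", re.IGNORECASE)


class CueLexiconScorer:
    """Transparent lexicon scorer: score 1.0 for a class iff a cue matches."""

    def __init__(self, cues: Mapping[str, Sequence[str]]):
        self._regexes = {
            label: [_cue_regex(c) for c in cue_list] for label, cue_list in cues.items()
        }

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._regexes)

    def __call__(self, text: str) -> dict[str, float]:
        return {
            label: 1.0 if any(rx.search(text) for rx in regexes) else 0.0
            for label, regexes in self._regexes.items()
        }

    @classmethod
    def default_emotions(cls) -> "CueLexiconScorer":
        return cls(resources.load_emotion_cues()["classes"])

    @classmethod
    def default_finer(cls) -> "CueLexiconScorer":
        return cls(resources.load_emotion_cues()["finer"])

    @classmethod
    def default_buckets(cls) -> "CueLexiconScorer":
        return cls(resources.load_emotion_cues()["buckets"])


EmotionModel = Callable[[str], Mapping[str, float]]


@dataclass
class EmotionLabelSet:
    post_id: str
    scores: dict[str, float] = field(default_factory=dict)
    labels: frozenset[str] = frozenset()


def classify_emotions(
    post: Post | str,
    model: EmotionModel | None = None,
    cutoff: float = 0.5,
) -> EmotionLabelSet:
    """Multilabel emotion classification for one post.

    Classes with score >= ``cutoff`` are set; ``neutral`` fires iff no other
    class does.
    """
    text = post.text if isinstance(post, Post) else post
    post_id = post.post_id if isinstance(post, Post) else ""
    model = model or _default_emotion_scorer()
    scores = dict(model(text))
    labels = {c for c, s in scores.items() if c != "neutral" and s >= cutoff}
    if not labels:
        labels = {"neutral"}
    return EmotionLabelSet(post_id, scores, frozenset(labels))


_EMOTION_SCORER: CueLexiconScorer | None = None
_BUCKET_SCORER: CueLexiconScorer | None = None


def _default_emotion_scorer() -> CueLexiconScorer:
    global _EMOTION_SCORER
    if _EMOTION_SCORER is None:
        _EMOTION_SCORER = CueLexiconScorer.default_emotions()
    return _EMOTION_SCORER


def _default_bucket_scorer() -> CueLexiconScorer:
    global _BUCKET_SCORER
    if _BUCKET_SCORER is None:
        _BUCKET_SCORER = CueLexiconScorer.default_buckets()
    return _BUCKET_SCORER


def classify_buckets(
    post: Post | str,
    model: EmotionModel | None = None,
    cutoff: float = 0.5,
) -> frozenset[str]:
    """Which high-risk sub-sentiment buckets fire for this post."""
    text = post.text if isinstance(post, Post) else post
    model = model or _default_bucket_scorer()
    scores = model(text)
    return frozenset(b for b, s in scores.items() if s >= cutoff)


class SubSentimentMap:
    """Bucket -> attribution-topic map for the high-risk cohort.

    Topics are theme-hierarchy nodes; in the default map every topic belongs
    to exactly one bucket.  Unknown buckets are fatal at load.
    """

    DEFAULT = {
        "concern": ("blood counts", "disease burden", "quality of life",
                    "treatment options", "disease progression"),
        "anxiety": ("diagnostic process",),
        "frustration": ("treatment modalities", "hematological management",
                        "navigating the health care system", "knowledge constraints"),
        "fear": ("health complications",),
        "confusion": ("disease understanding",),
        "information_seeking": ("treatment information", "ongoing research"),
    }

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        mapping = mapping or self.DEFAULT
        unknown = set(mapping) - set(HR_BUCKETS)
        if unknown:
            raise ValueError(f"unknown sub-sentiment buckets: {sorted(unknown)}")
        seen: dict[str, str] = {}
        for bucket, topics in mapping.items():
            for t in topics:
                if t in seen:
                    raise ValueError(
                        f"topic {t!r} attributed to both {seen[t]!r} and {bucket!r}")
                seen[t] = bucket
        self.mapping = {b: tuple(ts) for b, ts in mapping.items()}


def map_subsentiments(
    buckets: Collection[str],
    theme_labels: Collection[str],
    sub_map: SubSentimentMap | None = None,
) -> dict[str, frozenset[str]]:
    """Attribute each fired bucket to the post's matching themes.

    A bucket that fires with no mapped topic present keeps an empty
    attribution set; unlabeled posts produce no buckets.
    """
    sub_map = sub_map or SubSentimentMap()
    themes = set(theme_labels)
    return {
        b: frozenset(t for t in sub_map.mapping.get(b, ()) if t in themes)
        for b in buckets
    }


# ---------------------------------------------------------------------------
# Prevalence aggregation
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percentage(n: int, denominator: int) -> int:
    """Integer percentage with round-half-away-from-zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * n / denominator)


@dataclass(frozen=True)
class PrevalenceRow:
    label: str
    n: int
    pct: int


@dataclass
class PrevalenceTable:
    cohort: str
    denominator: int
    rows: list[PrevalenceRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.cohort, r.label, r.n, r.pct) for r in self.rows],
            columns=["cohort", "label", "n", "pct"],
        )

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {r.label: (r.n, r.pct) for r in self.rows}


def user_label_union(
    post_labels: Mapping[str, Collection[str]],
    posts_by_user: Mapping[str, Sequence[Post]],
    weights: Mapping[str, float] | None = None,
) -> dict[str, frozenset[str]]:
    """User-level label sets as the union of their posts' labels."""
    out: dict[str, frozenset[str]] = {}
    for user, posts in posts_by_user.items():
        labels: set[str] = set()
        for p in posts:
            if weights is not None and weights.get(p.post_id, 1.0) <= 0:
                continue
            labels |= set(post_labels.get(p.post_id, ()))
        out[user] = frozenset(labels)
    return out


def aggregate_prevalence(
    user_labels: Mapping[str, Collection[str]],
    cohort: Collection[str],
    cohort_name: str = "cohort",
    labels: Iterable[str] | None = None,
) -> PrevalenceTable:
    """Count users carrying each label within a cohort.

    ``n`` counts cohort users with the label (each user at most once
    regardless of posting volume); ``pct`` is the integer percentage of the
    cohort size, rounded half away from zero.  Rows sort by n descending,
    then label.  An empty cohort is fatal.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError(f"empty cohort {cohort_name!r}: cannot compute prevalence")
    denom = len(cohort)
    if labels is None:
        labels = sorted({l for u in cohort for l in user_labels.get(u, ())})
    rows = []
    for label in labels:
        n = sum(1 for u in cohort if label in user_labels.get(u, ()))
        rows.append(PrevalenceRow(label, n, percentage(n, denom)))
    rows.sort(key=lambda r: (-r.n, r.label))
    return PrevalenceTable(cohort_name, denom, rows)
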