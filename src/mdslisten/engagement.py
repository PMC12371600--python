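"""Engagement metrics, superuser normalization, thematic saturation, and the
pre/post-COVID split.

A superuser is one of the ~1% most prolific posters; their influence on
discussion-level aggregates is capped at a configurable number of posts per
discussion.  Saturation is the point in chronological processing after which
no new significant theme first appears within a look-ahead window.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from datetime import date
from typing import Collection, Iterable, Mapping, Sequence

from .corpus import Corpus, Post

__all__ = [
    "EngagementProfile",
    "SaturationCurve",
    "engagement_metrics",
    "detect_superusers",
    "normalize_superuser_influence",
    "saturation_analysis",
    "covid_split",
    "COVID_PRE_WINDOW",
    "COVID_POST_START",
]

# matched pre-pandemic window: January 2018 through February 2020; everything
# from March 2020 onward is the post-pandemic period
COVID_PRE_WINDOW = (date(2018, 1, 1), date(2020, 2, 29))
COVID_POST_START = date(2020, 3, 1)


@dataclass
class EngagementProfile:
    user_ref: str
    first_post: date
    last_post: date
    post_count: int
    is_superuser: bool = False
    weight: float = 1.0

    @property
    def active_span_days(self) -> int:
        return (self.last_post - self.first_post).days


def engagement_metrics(corpus: Corpus) -> tuple[dict[str, EngagementProfile], dict]:
    """Per-user activity profiles plus a min/median/max span summary."""
    profiles: dict[str, EngagementProfile] = {}
    for user, posts in corpus.posts_by_user().items():
        stamps = [p.timestamp for p in posts]
        profiles[user] = EngagementProfile(
            user_ref=user, first_post=min(stamps), last_post=max(stamps),
            post_count=len(posts))
    spans = [p.active_span_days for p in profiles.values()]
    summary = {
        "n_users": len(profiles),
        "min_span_days": min(spans) if spans else 0,
        "median_span_days": statistics.median(spans) if spans else 0,
        "max_span_days": max(spans) if spans else 0,
        "retention_2day_fraction": (
            sum(1 for s in spans if s <= 2) / len(spans) if spans else 0.0),
    }
    return profiles, summary


def detect_superusers(
    profiles: Mapping[str, EngagementProfile],
    fraction: float = 0.01,
) -> dict[str, EngagementProfile]:
    """Flag the top-``fraction`` of users by post count; ties at the cut
    are included."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if not profiles:
        return dict(profiles)
    ordered = sorted(profiles.values(), key=lambda p: (-p.post_count, p.user_ref))
    n_flag = -(-len(ordered) * fraction // 1)  # ceil
    n_flag = int(max(1, n_flag))
    cut_count = ordered[min(n_flag, len(ordered)) - 1].post_count
    for p in profiles.values():
        p.is_superuser = p.post_count >= cut_count
    return dict(profiles)


def normalize_superuser_influence(
    corpus: Corpus,
    profiles: Mapping[str, EngagementProfile],
    cap: int = 1,
) -> dict[str, float]:
    """Per-post weights capping superuser contributions per discussion.

    A superuser's earliest ``cap`` posts in each discussion keep weight 1;
    the rest get weight 0.  Non-superusers are untouched.  The weights are
    consumed by prevalence/network/sentiment aggregation, which skips
    zero-weight posts, so capping can only decrease aggregate counts.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    weights: dict[str, float] = {p.post_id: 1.0 for p in corpus.posts}
    for user, posts in corpus.posts_by_user().items():
        prof = profiles.get(user)
        if prof is None or not prof.is_superuser:
            continue
        prof.weight = min(1.0, cap / max(1, prof.post_count))
        by_thread: dict[str, list[Post]] = {}
        for p in posts:
            by_thread.setdefault(p.thread_id, []).append(p)
        for thread_posts in by_thread.values():
            ordered = sorted(thread_posts, key=lambda p: (p.timestamp, p.post_id))
            for p in ordered[cap:]:
                weights[p.post_id] = 0.0
    return weights


@dataclass
class SaturationCurve:
    batch_size: int
    lookahead: int
    cumulative: list[int] = field(default_factory=list)
    first_appearance: dict[str, int] = field(default_factory=dict)  # theme -> batch (1-based)
    saturation_index: int | None = None


def saturation_analysis(
    posts: Sequence[Post],
    assignments: Mapping[str, Iterable[str]],
    significant_themes: Collection[str],
    batch_size: int = 500,
    lookahead: int = 3,
) -> SaturationCurve:
    """Cumulative significant-theme discovery over chronological batches.

    The saturation index is the smallest batch ``b`` such that no significant
    theme first appears in batches ``(b, b+lookahead]``; the look-ahead window
    is truncated at the end of the corpus but must be non-empty, so a corpus
    whose every batch introduces a new theme has no saturation index.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    significant = set(significant_themes)
    ordered = sorted(posts, key=lambda p: (p.timestamp, p.post_id))
    batches = [ordered[i:i + batch_size] for i in range(0, len(ordered), batch_size)]
    curve = SaturationCurve(batch_size=batch_size, lookahead=lookahead)
    seen: set[str] = set()
    for b, batch in enumerate(batches, start=1):
        for post in batch:
            for theme in assignments.get(post.post_id, ()):
                if theme in significant and theme not in seen:
                    seen.add(theme)
                    curve.first_appearance[theme] = b
        curve.cumulative.append(len(seen))

    n = len(batches)
    for b in range(1, n):  # window (b, min(b+lookahead, n)] must be non-empty
        window_end = min(b + lookahead, n)
        if not any(b < fb <= window_end for fb in curve.first_appearance.values()):
            curve.saturation_index = b
            break
    return curve


def covid_split(posts: Sequence[Post]) -> dict[str, list[Post]]:
    """Partition posts into matched pre-pandemic, post-pandemic, and excluded.

    pre = [2018-01-01, 2020-02-29]; post = [2020-03-01, ...); anything
    earlier is excluded.  The three buckets partition the input exactly.
    """
    out: dict[str, list[Post]] = {"pre": [], "post": [], "excluded": []}
    for p in posts:
        if p.timestamp >= COVID_POST_START:
            out["post"].append(p)
        elif COVID_PRE_WINDOW[0] <= p.timestamp <= COVID_PRE_WINDOW[1]:
            out["pre"].append(p)
        else:
            out["excluded"].append(p)
    return out
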