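"""Engagement spans, superuser capping, saturation, COVID split."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from mdslisten import (covid_split, detect_superusers, engagement_metrics,
                       normalize_superuser_influence, saturation_analysis,
                       score_prevalence)
from mdslisten.corpus import Corpus, Post
from mdslisten.engagement import EngagementProfile


def _post(i, user="u", day=date(2015, 1, 1), thread="t1", text="hello"):
    return Post(post_id=f"p{i}", thread_id=thread, user_ref=user,
                timestamp=day, source="f", text=text)


def _corpus(posts):
    return Corpus(posts, {}, {}).with_posts(posts)


def _profiles(counts):
    return {
        u: EngagementProfile(u, date(2015, 1, 1), date(2015, 1, 1), c)
        for u, c in counts.items()
    }


class TestEngagementMetrics:
    def test_span_between_first_and_last_post(self):
        posts = [_post(1, day=date(2015, 1, 1)), _post(2, day=date(2015, 1, 11))]
        profiles, _ = engagement_metrics(_corpus(posts))
        assert profiles["u"].active_span_days == 10

    def test_single_post_user_has_zero_span(self):
        profiles, summary = engagement_metrics(_corpus([_post(1)]))
        assert profiles["u"].active_span_days == 0
        assert summary["median_span_days"] == 0

    def test_median_span_is_order_statistic(self):
        posts = []
        for i, span in enumerate([0, 2, 10, 40, 1200]):
            posts.append(_post(f"{i}a", user=f"u{i}", day=date(2010, 1, 1)))
            posts.append(_post(f"{i}b", user=f"u{i}",
                               day=date(2010, 1, 1) + timedelta(days=span)))
        _, summary = engagement_metrics(_corpus(posts))
        assert summary["median_span_days"] == 10
        assert summary["max_span_days"] == 1200


class TestSuperusers:
    def test_single_dominant_poster_flagged_at_one_percent(self):
        counts = {f"u{i}": 3 for i in range(99)}
        counts["big"] = 500
        profiles = detect_superusers(_profiles(counts), fraction=0.01)
        flagged = {u for u, p in profiles.items() if p.is_superuser}
        assert flagged == {"big"}

    def test_tie_group_at_cut_is_included(self):
        counts = {"a": 10, "b": 10, "c": 10, "d": 1}
        profiles = detect_superusers(_profiles(counts), fraction=0.25)
        flagged = {u for u, p in profiles.items() if p.is_superuser}
        assert flagged == {"a", "b", "c"}

    def test_uniform_counts_flag_everyone(self):
        counts = {f"u{i}": 5 for i in range(10)}
        profiles = detect_superusers(_profiles(counts), fraction=0.2)
        assert all(p.is_superuser for p in profiles.values())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            detect_superusers(_profiles({"u": 1}), fraction=0.0)


class TestNormalization:
    def test_superuser_capped_to_one_post_per_discussion(self):
        posts = [_post(i, user="su", day=date(2015, 1, 1) + timedelta(days=i))
                 for i in range(30)]
        corpus = _corpus(posts)
        profiles, _ = engagement_metrics(corpus)
        profiles["su"].is_superuser = True
        weights = normalize_superuser_influence(corpus, profiles, cap=1)
        assert sum(weights.values()) == 1.0
        assert weights["p0"] == 1.0  # earliest post kept

    def test_non_superuser_untouched(self):
        posts = [_post(i, user="reg") for i in range(30)]
        corpus = _corpus(posts)
        profiles, _ = engagement_metrics(corpus)
        weights = normalize_superuser_influence(corpus, profiles, cap=1)
        assert sum(weights.values()) == 30.0

    def test_capping_never_increases_prevalence(self, medium_corpus):
        corpus, _ = medium_corpus
        profiles, _ = engagement_metrics(corpus)
        detect_superusers(profiles, 0.01)
        weights = normalize_superuser_influence(corpus, profiles, cap=1)
        assignments = {p.post_id: {w for w in ("A", "B") if hash(p.post_id + w) % 3}
                       for p in corpus.posts}
        discussion_of = {p.post_id: p.thread_id for p in corpus.posts}
        before = score_prevalence(assignments, discussion_of)
        after = score_prevalence(assignments, discussion_of, weights)
        for theme, n in after.items():
            assert n <= before[theme]


def _schedule_posts(schedule):
    """One post per slot; schedule[i] = themes of post i (batch size 1)."""
    posts, assignments = [], {}
    for i, themes in enumerate(schedule):
        p = _post(i, day=date(2015, 1, 1) + timedelta(days=i))
        posts.append(p)
        assignments[p.post_id] = set(themes)
    return posts, assignments


class TestSaturation:
    def test_everything_in_first_batch_saturates_at_one(self):
        posts, assignments = _schedule_posts([{"A", "B"}, {"A"}, {"B"}, {"A"}])
        curve = saturation_analysis(posts, assignments, {"A", "B"},
                                    batch_size=1, lookahead=3)
        assert curve.saturation_index == 1
        assert curve.cumulative == [2, 2, 2, 2]

    def test_new_theme_every_batch_never_saturates(self):
        schedule = [{f"T{i}"} for i in range(5)]
        posts, assignments = _schedule_posts(schedule)
        curve = saturation_analysis(posts, assignments,
                                    {f"T{i}" for i in range(5)},
                                    batch_size=1, lookahead=2)
        assert curve.saturation_index is None

    def test_last_new_theme_batch_is_the_saturation_index(self):
        schedule = [{"A"}, {"B"}, {"A"}, {"C"}, {"A"}, {"B"}, {"C"}, {"A"}]
        posts, assignments = _schedule_posts(schedule)
        curve = saturation_analysis(posts, assignments, {"A", "B", "C"},
                                    batch_size=1, lookahead=10)
        assert curve.first_appearance == {"A": 1, "B": 2, "C": 4}
        assert curve.saturation_index == 4

    def test_curve_is_nondecreasing_and_bounded(self, medium_corpus):
        from mdslisten import assign_corpus_themes
        corpus, _ = medium_corpus
        assignments = {pid: a.theme_set
                       for pid, a in assign_corpus_themes(corpus).items()}
        significant = {"blood counts", "quality of life", "treatment options"}
        curve = saturation_analysis(corpus.posts, assignments, significant,
                                    batch_size=200, lookahead=3)
        assert all(a <= b for a, b in zip(curve.cumulative, curve.cumulative[1:]))
        assert curve.cumulative[-1] <= len(significant)


class TestCovidSplit:
    @pytest.mark.parametrize("day,bucket", [
        (date(2019, 6, 15), "pre"),
        (date(2020, 3, 1), "post"),   # first post-pandemic day
        (date(2020, 2, 29), "pre"),   # last matched pre-pandemic day
        (date(2018, 1, 1), "pre"),    # window start inclusive
        (date(2017, 12, 31), "excluded"),
        (date(2022, 5, 5), "post"),
    ])
    def test_boundaries(self, day, bucket):
        split = covid_split([_post(1, day=day)])
        assert [p.post_id for p in split[bucket]] == ["p1"]

    def test_split_partitions_the_corpus(self, medium_corpus):
        corpus, _ = medium_corpus
        split = covid_split(corpus.posts)
        assert sum(len(v) for v in split.values()) == corpus.n_posts
        ids = [p.post_id for v in split.values() for p in v]
        assert len(ids) == len(set(ids))
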