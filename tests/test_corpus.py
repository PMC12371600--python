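"""Corpus I/O, deduplication, spell cleaning, and exclusion filters."""

from __future__ import annotations

import json
from datetime import date

import pytest

from mdslisten.corpus import (CorpusLoadError, ExclusionRules, Post,
                              SpellDictionary, apply_exclusion_filters,
                              clean_text, deduplicate, load_corpus, write_corpus)


def _rec(i, **kw):
    rec = {"post_id": f"p{i}", "thread_id": "t0", "user_ref": f"u{i}",
           "timestamp": "2015-03-02", "source": "forum", "text": f"hello {i}"}
    rec.update(kw)
    return rec


def _post(i, user="u1", text="hello world", day=date(2015, 3, 2), thread="t0"):
    return Post(post_id=f"p{i}", thread_id=thread, user_ref=user,
                timestamp=day, source="forum", text=text)


class TestLoad:
    def test_wellformed_records_load_identically(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text("\n".join(json.dumps(_rec(i)) for i in range(3)))
        corpus = load_corpus(path)
        assert corpus.n_posts == 3
        assert corpus.provenance["records_skipped"] == 0

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text("")
        corpus = load_corpus(path)
        assert corpus.n_posts == corpus.n_threads == corpus.n_users == 0

    def test_record_missing_timestamp_is_skipped_and_logged(self, tmp_path):
        recs = [_rec(0), {k: v for k, v in _rec(1).items() if k != "timestamp"}, _rec(2)]
        path = tmp_path / "c.jsonl"
        path.write_text("\n".join(json.dumps(r) for r in recs))
        corpus = load_corpus(path)
        assert corpus.n_posts == 2
        assert corpus.provenance["records_skipped"] == 1
        assert "timestamp" in corpus.provenance["skip_log"][0]

    def test_mostly_malformed_file_is_fatal(self, tmp_path):
        recs = [_rec(0)] + [{"post_id": f"x{i}"} for i in range(3)]
        path = tmp_path / "c.jsonl"
        path.write_text("\n".join(json.dumps(r) for r in recs))
        with pytest.raises(CorpusLoadError):
            load_corpus(path)

    def test_month_resolution_dates_resolve_to_day_one(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(json.dumps(_rec(0, timestamp="2015-07")))
        corpus = load_corpus(path)
        assert corpus.posts[0].timestamp == date(2015, 7, 1)

    @pytest.mark.parametrize("fmt", ["jsonl", "csv"])
    def test_write_load_roundtrip_is_bit_identical(self, tmp_path, fmt, small_corpus):
        corpus, _ = small_corpus
        p1 = tmp_path / f"a.{fmt}"
        p2 = tmp_path / f"b.{fmt}"
        write_corpus(corpus, p1, format=fmt)
        write_corpus(load_corpus(p1, format=fmt), p2, format=fmt)
        assert p1.read_bytes() == p2.read_bytes()

    def test_thread_counts_match_posts(self, small_corpus):
        corpus, _ = small_corpus
        by_thread = corpus.posts_by_thread()
        for tid, thread in corpus.threads.items():
            assert thread.n_posts == len(by_thread[tid])


class TestDeduplicate:
    def test_distinct_texts_unchanged(self):
        corpus = _post(1).__class__  # noqa: just build via helper below
        from mdslisten.corpus import Corpus
        posts = [_post(1, text="a"), _post(2, text="b"), _post(3, text="c")]
        c = Corpus(posts, {}, {}).with_posts(posts)
        assert deduplicate(c).n_posts == 3

    def test_same_user_same_text_collapses_to_earliest(self):
        from mdslisten.corpus import Corpus
        posts = [_post(1, text="Hello  World", day=date(2015, 5, 1)),
                 _post(2, text="hello world", day=date(2015, 3, 1)),
                 _post(3, text="other")]
        c = Corpus(posts, {}, {}).with_posts(posts)
        out = deduplicate(c)
        assert out.n_posts == 2
        kept = {p.post_id for p in out.posts}
        assert "p2" in kept and "p1" not in kept  # earliest copy retained
        assert out.provenance["dedup_removed"] == 1

    def test_identical_text_from_different_users_both_retained(self):
        from mdslisten.corpus import Corpus
        posts = [_post(1, user="alice", text="same words"),
                 _post(2, user="bob", text="same words")]
        c = Corpus(posts, {}, {}).with_posts(posts)
        assert deduplicate(c).n_posts == 2

    def test_idempotent_on_synthetic_corpus(self, small_corpus):
        corpus, _ = small_corpus
        once = deduplicate(corpus)
        twice = deduplicate(once)
        assert twice.n_posts == once.n_posts
        assert twice.provenance["dedup_removed"] == 0


class TestCleanText:
    def test_in_dictionary_text_unchanged(self, dictionary):
        post = _post(1, text="the doctor said we wait for results")
        res = clean_text(post, dictionary)
        assert res.post.text == post.text
        assert res.corrections == []

    def test_misspelling_corrected_at_edit_distance_one(self, dictionary):
        res = clean_text(_post(1, text="I hope to recieve the results"), dictionary)
        assert "receive" in res.post.text
        assert ("recieve", "receive") in res.corrections

    def test_capitalization_preserved(self, dictionary):
        res = clean_text(_post(1, text="Recieve it"), dictionary)
        assert res.post.text.startswith("Receive")

    def test_invalid_encoding_flagged_for_exclusion(self, dictionary):
        bad = "hello \udcff world"  # lone surrogate from a bad byte sequence
        res = clean_text(_post(1, text=bad), dictionary)
        assert not res.encoding_valid

    def test_never_increases_token_count_nor_touches_known_words(
            self, dictionary, small_corpus):
        import re
        corpus, _ = small_corpus
        for post in corpus.posts[:200]:
            res = clean_text(post, dictionary)
            before = re.findall(r"[A-Za-z']+", post.text)
            after = re.findall(r"[A-Za-z']+", res.post.text)
            assert len(after) <= len(before)
            for b, a in zip(before, after):
                if b in dictionary:
                    assert a == b

    def test_ties_break_by_frequency_then_lexicographic(self):
        d = SpellDictionary({"cat": 5, "car": 5, "cab": 9})
        # "caz" has three candidates; highest frequency wins
        assert d.best_correction("caz") == "cab"
        d2 = SpellDictionary({"cat": 5, "car": 5})
        assert d2.best_correction("caz") == "car"  # lexicographic on tie


class TestExclusionFilters:
    def _corpus(self, posts):
        from mdslisten.corpus import Corpus
        return Corpus(posts, {}, {}).with_posts(posts)

    def test_window_is_inclusive_at_both_ends(self):
        rules = ExclusionRules(window=(date(2010, 1, 1), date(2012, 12, 31)))
        posts = [_post(1, day=date(2009, 12, 31)),   # before -> removed
                 _post(2, day=date(2010, 1, 1)),     # on start -> retained
                 _post(3, day=date(2012, 12, 31)),   # on end -> retained
                 _post(4, day=date(2013, 1, 1))]     # after -> removed
        out = apply_exclusion_filters(self._corpus(posts), rules)
        assert {p.post_id for p in out.posts} == {"p2", "p3"}
        assert out.provenance["exclusions"]["window"] == 2

    def test_news_cue_post_removed(self):
        posts = [_post(1, text="Sharing a news article I found."),
                 _post(2, text="I have MDS and feel fine.")]
        out = apply_exclusion_filters(self._corpus(posts))
        assert [p.post_id for p in out.posts] == ["p2"]
        assert out.provenance["exclusions"]["news"] == 1

    def test_all_retained_posts_inside_window(self, small_corpus):
        corpus, _ = small_corpus
        out = apply_exclusion_filters(corpus)
        lo, hi = out.study_window
        assert all(lo <= p.timestamp <= hi for p in out.posts)
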