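"""Forum corpus data model, I/O, cleaning, and inclusion/exclusion filters.

A corpus is a flat collection of :class:`Post` records plus derived
:class:`Thread` and :class:`User` tables.  Posts are exchanged as
line-delimited JSON (one object per line) or as a delimited table with a
header row; both are UTF-8.

Cleaning follows the conventions of forum-scrape studies: duplicate posts
(same author, same normalized text) are collapsed onto the earliest copy,
posts that fail UTF-8 validation are flagged for exclusion, and
out-of-dictionary tokens are autocorrected to their single best in-dictionary
neighbour at small edit distance.
"""

from __future__ import annotations

import csv
import io
import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Post",
    "Thread",
    "User",
    "Corpus",
    "CorpusLoadError",
    "SpellDictionary",
    "CleanResult",
    "ExclusionRules",
    "load_corpus",
    "write_corpus",
    "deduplicate",
    "clean_text",
    "clean_corpus",
    "apply_exclusion_filters",
]

DEFAULT_STUDY_WINDOW = (date(2008, 1, 1), date(2022, 12, 31))

ROLE_LABELS = ("patient", "caregiver", "other", "unknown")
RISK_LABELS = ("low", "intermediate", "high", "very_high", "unknown")


class CorpusLoadError(ValueError):
    """Raised when a corpus file is unreadable or mostly malformed."""


@dataclass(frozen=True)
class Post:
    """One forum post.

    ``timestamp`` is day-resolution; month-only dates resolve to day 1 at
    parse time.  ``user_ref`` is a raw username before anonymization and a
    tokenized handle after.
    """

    post_id: str
    thread_id: str
    user_ref: str
    timestamp: date
    source: str
    text: str
    url: str | None = None
    reply_to: str | None = None


@dataclass
class Thread:
    thread_id: str
    title: str = ""
    source: str = ""
    n_posts: int = 0
    n_views: int | None = None


@dataclass
class User:
    user_ref: str
    join_date: date | None = None
    location: str | None = None
    role: str = "unknown"
    risk: str = "unknown"


@dataclass
class Corpus:
    """Posts plus derived thread/user tables and a provenance log."""

    posts: list[Post]
    threads: dict[str, Thread]
    users: dict[str, User]
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    provenance: dict = field(default_factory=dict)

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def n_threads(self) -> int:
        return len(self.threads)

    @property
    def n_users(self) -> int:
        return len(self.users)

    def posts_by_user(self) -> dict[str, list[Post]]:
        out: dict[str, list[Post]] = {}
        for p in self.posts:
            out.setdefault(p.user_ref, []).append(p)
        return out

    def posts_by_thread(self) -> dict[str, list[Post]]:
        out: dict[str, list[Post]] = {}
        for p in self.posts:
            out.setdefault(p.thread_id, []).append(p)
        return out

    def with_posts(self, posts: Sequence[Post], note: str | None = None) -> "Corpus":
        """Return a new corpus over ``posts`` with rebuilt thread/user tables."""
        threads = _rebuild_threads(posts, self.threads)
        users = _rebuild_users(posts, self.users)
        prov = dict(self.provenance)
        if note:
            prov.setdefault("log", []).append(note)
        return Corpus(list(posts), threads, users, self.study_window, prov)


def _rebuild_threads(posts: Sequence[Post], old: Mapping[str, Thread]) -> dict[str, Thread]:
    counts = Counter(p.thread_id for p in posts)
    threads: dict[str, Thread] = {}
    for p in posts:
        if p.thread_id not in threads:
            prev = old.get(p.thread_id)
            threads[p.thread_id] = Thread(
                thread_id=p.thread_id,
                title=prev.title if prev else "",
                source=p.source,
                n_posts=counts[p.thread_id],
                n_views=prev.n_views if prev else None,
            )
    return threads


def _rebuild_users(posts: Sequence[Post], old: Mapping[str, User]) -> dict[str, User]:
    users: dict[str, User] = {}
    for p in posts:
        if p.user_ref not in users:
            prev = old.get(p.user_ref)
            users[p.user_ref] = (
                replace_user(prev) if prev else User(user_ref=p.user_ref)
            )
    return users


def replace_user(u: User) -> User:
    return User(u.user_ref, u.join_date, u.location, u.role, u.risk)


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("post_id", "thread_id", "user_ref", "timestamp", "source", "text")


def parse_date(value: str) -> date:
    """Parse an ISO date; ``YYYY-MM`` resolves to day 1."""
    value = str(value).strip()
    for fmt in ("%Y-%m-%d", "%Y/%m/%d"):
        try:
            return datetime.strptime(value, fmt).date()
        except ValueError:
            pass
    m = re.fullmatch(r"(\d{4})-(\d{1,2})", value)
    if m:
        return date(int(m.group(1)), int(m.group(2)), 1)
    raise ValueError(f"unparseable date: {value!r}")


def _record_to_post(rec: Mapping[str, object]) -> Post:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] in (None, ""):
            raise ValueError(f"missing required field {f!r}")
    return Post(
        post_id=str(rec["post_id"]),
        thread_id=str(rec["thread_id"]),
        user_ref=str(rec["user_ref"]),
        timestamp=parse_date(str(rec["timestamp"])),
        source=str(rec["source"]),
        text=str(rec["text"]),
        url=str(rec["url"]) if rec.get("url") else None,
        reply_to=str(rec["reply_to"]) if rec.get("reply_to") else None,
    )


def _post_to_record(p: Post) -> dict:
    rec = {
        "post_id": p.post_id,
        "thread_id": p.thread_id,
        "user_ref": p.user_ref,
        "timestamp": p.timestamp.isoformat(),
        "source": p.source,
        "text": p.text,
    }
    if p.url:
        rec["url"] = p.url
    if p.reply_to:
        rec["reply_to"] = p.reply_to
    return rec


def load_corpus(
    path: str | Path,
    format: str = "jsonl",
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
) -> Corpus:
    """Load a corpus from a JSONL or CSV posts file.

    Malformed records (missing fields, bad timestamps, duplicate post ids)
    are skipped and counted in ``provenance``.  More than 50% malformed
    records is treated as a broken file and raises :class:`CorpusLoadError`.
    """
    path = Path(path)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise CorpusLoadError(f"cannot read {path}: {exc}") from exc
    text = raw.decode("utf-8", errors="surrogateescape")

    records: list[Mapping[str, object]] = []
    parse_failures = 0
    if format == "jsonl":
        for line in text.splitlines():
            if not line.strip():
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                parse_failures += 1
    else:
        reader = csv.DictReader(io.StringIO(text))
        records = list(reader)

    posts: list[Post] = []
    seen_ids: set[str] = set()
    skipped: list[str] = []
    for i, rec in enumerate(records):
        try:
            post = _record_to_post(rec)
        except ValueError as exc:
            skipped.append(f"record {i}: {exc}")
            continue
        if post.post_id in seen_ids:
            skipped.append(f"record {i}: duplicate post_id {post.post_id!r}")
            continue
        seen_ids.add(post.post_id)
        posts.append(post)

    total = len(records) + parse_failures
    malformed = len(skipped) + parse_failures
    if total > 0 and malformed > total / 2:
        raise CorpusLoadError(
            f"{path}: {malformed}/{total} records malformed; refusing to load"
        )

    prov = {
        "path": str(path),
        "format": format,
        "records_read": total,
        "records_skipped": malformed,
        "skip_log": skipped,
        "sources": sorted({p.source for p in posts}),
        "log": [],
    }
    return Corpus(posts, _rebuild_threads(posts, {}), _rebuild_users(posts, {}),
                  study_window, prov)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write posts canonically (fixed field order) so round-trips are exact."""
    path = Path(path)
    if format == "jsonl":
        lines = [json.dumps(_post_to_record(p), ensure_ascii=False, sort_keys=False)
                 for p in corpus.posts]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "csv":
        cols = ["post_id", "thread_id", "user_ref", "timestamp", "source", "text",
                "url", "reply_to"]
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for p in corpus.posts:
                rec = _post_to_record(p)
                writer.writerow({c: rec.get(c, "") for c in cols})
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _normalize_text(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def deduplicate(corpus: Corpus) -> Corpus:
    """Collapse duplicate posts.

    The duplicate key is ``(user_ref, whitespace/case-normalized text)``:
    cross-posting by the same author is the dominant duplication mode on
    forums, and distinct users quoting the same text are not duplicates.
    The earliest-timestamped copy is retained (input order breaks ties).
    """
    best: dict[tuple[str, str], Post] = {}
    order: list[tuple[str, str]] = []
    for p in corpus.posts:
        key = (p.user_ref, _normalize_text(p.text))
        if key not in best:
            best[key] = p
            order.append(key)
        elif p.timestamp < best[key].timestamp:
            best[key] = p
    kept = [best[k] for k in order]
    removed = len(corpus.posts) - len(kept)
    out = corpus.with_posts(kept, note=f"deduplicate: removed {removed}")
    out.provenance["dedup_removed"] = removed
    return out


# ---------------------------------------------------------------------------
# Spell correction and encoding validation
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[A-Za-z']+")
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _edits1(word: str) -> set[str]:
    """All strings within Damerau-Levenshtein distance 1 of ``word``."""
    splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
    deletes = {L + R[1:] for L, R in splits if R}
    transposes = {L + R[1] + R[0] + R[2:] for L, R in splits if len(R) > 1}
    replaces = {L + c + R[1:] for L, R in splits if R for c in _ALPHABET}
    inserts = {L + c + R for L, R in splits for c in _ALPHABET}
    return deletes | transposes | replaces | inserts


class SpellDictionary:
    """Word list with frequencies used by the autocorrector.

    Correction candidates are in-dictionary words within edit distance 1
    (2 if configured); ties break by frequency (descending) then
    lexicographic order.
    """

    def __init__(self, word_freq: Mapping[str, int]):
        if not word_freq:
            raise ValueError("dictionary must be non-empty")
        self._freq = {w.lower(): int(f) for w, f in word_freq.items()}

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "SpellDictionary":
        return cls({w: 1 for w in words})

    @classmethod
    def from_file(cls, path: str | Path) -> "SpellDictionary":
        freq: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            parts = line.split()
            if not parts:
                continue
            freq[parts[0]] = int(parts[1]) if len(parts) > 1 else 1
        return cls(freq)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._freq

    def __len__(self) -> int:
        return len(self._freq)

    def best_correction(self, token: str, max_edit_distance: int = 1) -> str | None:
        low = token.lower()
        if low in self._freq:
            return None
        candidates = {w for w in _edits1(low) if w in self._freq}
        if not candidates and max_edit_distance >= 2:
            for e1 in _edits1(low):
                candidates.update(w for w in _edits1(e1) if w in self._freq)
        if not candidates:
            return None
        return min(candidates, key=lambda w: (-self._freq[w], w))


@dataclass
class CleanResult:
    post: Post
    corrections: list[tuple[str, str]]
    encoding_valid: bool


def _utf8_valid(text: str) -> bool:
    try:
        text.encode("utf-8")
    except UnicodeEncodeError:  # lone surrogates from a bad byte sequence
        return False
    return True


def clean_text(post: Post, dictionary: SpellDictionary,
               max_edit_distance: int = 1) -> CleanResult:
    """Validate encoding and autocorrect out-of-dictionary tokens.

    Posts whose text is not valid UTF-8 are flagged (``encoding_valid``
    False) for exclusion.  In-dictionary tokens are never altered; an
    out-of-dictionary token is replaced only when a best in-dictionary
    correction exists within ``max_edit_distance``.
    """
    if not _utf8_valid(post.text):
        return CleanResult(post, [], encoding_valid=False)

    corrections: list[tuple[str, str]] = []

    def fix(m: re.Match) -> str:
        tok = m.group(0)
        corr = dictionary.best_correction(tok, max_edit_distance)
        if corr is None:
            return tok
        if tok[:1].isupper():
            corr = corr.capitalize()
        corrections.append((tok, corr))
        return corr

    new_text = _WORD_RE.sub(fix, post.text)
    new_post = post if new_text == post.text else replace(post, text=new_text)
    return CleanResult(new_post, corrections, encoding_valid=True)


def clean_corpus(corpus: Corpus, dictionary: SpellDictionary,
                 max_edit_distance: int = 1) -> Corpus:
    """Apply :func:`clean_text` corpus-wide, dropping encoding-invalid posts."""
    kept: list[Post] = []
    n_corrected = 0
    n_invalid = 0
    for p in corpus.posts:
        res = clean_text(p, dictionary, max_edit_distance)
        if not res.encoding_valid:
            n_invalid += 1
            continue
        if res.corrections:
            n_corrected += 1
        kept.append(res.post)
    out = corpus.with_posts(
        kept, note=f"clean: {n_corrected} corrected, {n_invalid} invalid encoding")
    out.provenance["encoding_invalid_removed"] = n_invalid
    out.provenance["posts_spell_corrected"] = n_corrected
    return out


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------

DEFAULT_NEWS_CUES = (
    "press release",
    "news article",
    "researchers announced",
    "study published",
    "according to the article",
    "in the news",
)

DEFAULT_APPROVAL_CUES = (
    "fda approves",
    "fda approval",
    "approved by the fda",
    "drug approval",
    "label expansion",
)


@dataclass
class ExclusionRules:
    """Textual-cue and date-window exclusion rules.

    The window is inclusive at both endpoints.  Cue matching is
    case-insensitive substring matching; cue lists target posts without
    personal patient/caregiver experience (news or article reposts, drug
    approval announcements).
    """

    window: tuple[date, date] | None = None
    news_cues: tuple[str, ...] = DEFAULT_NEWS_CUES
    approval_cues: tuple[str, ...] = DEFAULT_APPROVAL_CUES


def apply_exclusion_filters(corpus: Corpus, rules: ExclusionRules | None = None) -> Corpus:
    """Remove posts matching any exclusion rule; count removals per rule."""
    rules = rules or ExclusionRules()
    window = rules.window or corpus.study_window
    counts: dict[str, int] = {"window": 0, "news": 0, "approval": 0}
    kept: list[Post] = []
    for p in corpus.posts:
        if not (window[0] <= p.timestamp <= window[1]):
            counts["window"] += 1
            continue
        low = p.text.lower()
        if any(cue in low for cue in rules.news_cues):
            counts["news"] += 1
            continue
        if any(cue in low for cue in rules.approval_cues):
            counts["approval"] += 1
            continue
        kept.append(p)
    out = corpus.with_posts(kept, note=f"exclusion filters: removed {counts}")
    out.study_window = window
    out.provenance["exclusions"] = counts
    return out
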