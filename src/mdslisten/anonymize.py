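"""De-identification: name/manufacturer substitution, brand->INN
normalization, username tokenization, contact-detail scrubbing, and
exclusion of clinical-trial / investigational-drug posts.

Name detection is lexicon- and title-driven (no NER model): person names are
matched against bundled given-name/surname lists, provider mentions as a
professional title followed by a capitalized name, and manufacturers against
a fixed list.  Allowlisted institutions (NCI, Dana Farber, ...) are retained
verbatim.  Every replacement is recorded in a :class:`ScrubAudit` whose
actions, replayed against the original text, reproduce the scrubbed text.
"""

from __future__ import annotations

import hashlib
import hmac
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import resources
from .corpus import Corpus, Post

__all__ = [
    "BrandMap",
    "PiiLexicon",
    "ScrubAction",
    "ScrubAudit",
    "scrub_pii",
    "map_brand_to_inn",
    "tokenize_username",
    "filter_trial_posts",
    "anonymize_corpus",
]


class BrandMap:
    """Brand name -> International Nonproprietary Name mapping.

    Keys are unique case-insensitively and INN values lowercase; the bundled
    default covers the standard brand->INN conversion table (Venclexta ->
    venetoclax etc.) and is extensible.
    """

    def __init__(self, entries: Mapping[str, str]):
        if not entries:
            raise ValueError("brand map must be non-empty")
        seen: set[str] = set()
        self.entries: dict[str, str] = {}
        for brand, inn in entries.items():
            low = brand.lower()
            if low in seen:
                raise ValueError(f"duplicate brand key (case-insensitive): {brand!r}")
            seen.add(low)
            self.entries[brand] = inn.lower()
        pattern = "|".join(
            re.escape(b) for b in sorted(self.entries, key=len, reverse=True)
        )
        self._regex = re.compile(rf"\b(?:{pattern})\b", re.IGNORECASE)
        self._by_lower = {b.lower(): inn for b, inn in self.entries.items()}

    @classmethod
    def default(cls) -> "BrandMap":
        return cls(resources.load_brand_map_table())

    def lookup(self, brand: str) -> str | None:
        return self._by_lower.get(brand.lower())

    def substitute(self, text: str) -> str:
        return self._regex.sub(lambda m: self._by_lower[m.group(0).lower()], text)


def map_brand_to_inn(text: str, brand_map: BrandMap) -> str:
    """Replace every whole-word, case-insensitive brand occurrence by its INN.

    Idempotent: INNs are not keys, so a second pass is the identity.
    """
    return brand_map.substitute(text)


@dataclass
class PiiLexicon:
    """Name lists and allowlist driving lexicon-based PII scrubbing."""

    given_names: tuple[str, ...]
    surnames: tuple[str, ...]
    provider_titles: tuple[str, ...] = ("Dr", "Doctor", "Prof", "Professor", "Nurse")
    institutions: tuple[str, ...] = ()
    manufacturers: tuple[str, ...] = ()

    def __post_init__(self):
        names = {n.lower() for n in self.given_names} | {n.lower() for n in self.surnames}
        overlap = names & {i.lower() for i in self.institutions}
        if overlap:
            raise ValueError(f"institution allowlist overlaps name lists: {overlap}")

    @classmethod
    def default(cls) -> "PiiLexicon":
        return cls(
            given_names=tuple(resources.load_given_names()),
            surnames=tuple(resources.load_surnames()),
            institutions=tuple(resources.load_institutions()),
            manufacturers=tuple(resources.load_manufacturers()),
        )


@dataclass(frozen=True)
class ScrubAction:
    start: int
    end: int
    category: str  # NAME, PROVIDER NAME, PRODUCT MANUFACTURER, EMAIL, PHONE, URL, BRAND
    original: str
    replacement: str


@dataclass
class ScrubAudit:
    actions: list[ScrubAction] = field(default_factory=list)

    def apply(self, original: str) -> str:
        """Replay the recorded replacements against ``original``."""
        out = original
        for act in sorted(self.actions, key=lambda a: a.start, reverse=True):
            out = out[: act.start] + act.replacement + out[act.end :]
        return out


_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.\-]+\b")
_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_PHONE_RE = re.compile(
    r"(?:\+?1[\s.\-]?)?(?:\(\d{3}\)\s?|\d{3}[\s.\-])\d{3}[\s.\-]\d{4}\b"
)
_CAPWORD = r"[A-Z][a-z]+"


def _find_spans(regex: re.Pattern, text: str, category: str, replacement: str):
    for m in regex.finditer(text):
        yield ScrubAction(m.start(), m.end(), category, m.group(0), replacement)


def scrub_pii(text: str, lexicon: PiiLexicon) -> tuple[str, ScrubAudit]:
    """Scrub personal identifiers from free text.

    Person names become "NAME", title+name provider mentions "PROVIDER NAME",
    manufacturer names "PRODUCT MANUFACTURER"; emails, phone numbers, and
    links are removed.  Allowlisted institutions are untouched.  The
    operation is idempotent (replacement labels are never re-matched).
    """
    protected: list[tuple[int, int]] = []
    if lexicon.institutions:
        inst_re = re.compile(
            r"\b(?:" + "|".join(re.escape(i) for i in
                                sorted(lexicon.institutions, key=len, reverse=True))
            + r")\b",
            re.IGNORECASE,
        )
        protected = [(m.start(), m.end()) for m in inst_re.finditer(text)]

    def clear(start: int, end: int, taken: list[tuple[int, int]]) -> bool:
        return all(end <= s or start >= e for s, e in protected) and all(
            end <= s or start >= e for s, e in taken
        )

    candidates: list[ScrubAction] = []
    candidates += _find_spans(_EMAIL_RE, text, "EMAIL", "")
    candidates += _find_spans(_URL_RE, text, "URL", "")
    candidates += _find_spans(_PHONE_RE, text, "PHONE", "")

    titles = "|".join(re.escape(t) for t in lexicon.provider_titles)
    provider_re = re.compile(
        rf"\b(?:{titles})\.?\s+{_CAPWORD}(?:\s+{_CAPWORD})?"
    )
    candidates += _find_spans(provider_re, text, "PROVIDER NAME", "PROVIDER NAME")

    names = sorted(set(lexicon.given_names) | set(lexicon.surnames),
                   key=len, reverse=True)
    if names:
        # consecutive name-list tokens ("Jane Smith") collapse to one NAME
        name_alt = "|".join(re.escape(n) for n in names)
        name_re = re.compile(rf"\b(?:{name_alt})(?:\s+(?:{name_alt}))*\b")
        candidates += _find_spans(name_re, text, "NAME", "NAME")

    if lexicon.manufacturers:
        manu_re = re.compile(
            r"\b(?:" + "|".join(re.escape(m) for m in
                                sorted(lexicon.manufacturers, key=len, reverse=True))
            + r")\b",
            re.IGNORECASE,
        )
        candidates += _find_spans(manu_re, text, "PRODUCT MANUFACTURER",
                                  "PRODUCT MANUFACTURER")

    # priority: contact details, then provider mentions, then names, then
    # manufacturers; earlier-accepted spans win on overlap
    accepted: list[ScrubAction] = []
    taken: list[tuple[int, int]] = []
    for act in candidates:
        if clear(act.start, act.end, taken):
            accepted.append(act)
            taken.append((act.start, act.end))

    audit = ScrubAudit(sorted(accepted, key=lambda a: a.start))
    return audit.apply(text), audit


# ---------------------------------------------------------------------------
# Username tokenization
# ---------------------------------------------------------------------------

TOKEN_LENGTH = 12


def _shares_substring(token: str, user_ref: str, k: int = 3) -> bool:
    low_tok, low_ref = token.lower(), user_ref.lower()
    return any(low_ref[i : i + k] in low_tok for i in range(len(low_ref) - k + 1))


def tokenize_username(user_ref: str, salt: str) -> str:
    """Deterministic keyed-hash token for a username.

    Same ``(user_ref, salt)`` always yields the same token, preserving
    longitudinality.  The token is a fixed-length hex prefix of an HMAC and
    is re-derived (with a counter) in the rare case it shares a >=3-character
    substring with the original username, so the token never reveals any
    part of it.
    """
    if not user_ref:
        raise ValueError("user_ref must be non-empty")
    counter = 0
    while True:
        msg = user_ref if counter == 0 else f"{user_ref}\x00{counter}"
        token = hmac.new(salt.encode("utf-8"), msg.encode("utf-8"),
                         hashlib.sha256).hexdigest()[:TOKEN_LENGTH]
        if len(user_ref) < 3 or not _shares_substring(token, user_ref):
            return token
        counter += 1


# ---------------------------------------------------------------------------
# Clinical-trial / investigational-drug filtering
# ---------------------------------------------------------------------------

_PARTICIPATION_RE = re.compile(
    r"\bi\s+(?:have\s+|was\s+|am\s+)?"
    r"(?:joined|started|enrolled|signed\s+up|decided\s+to\s+start|began|"
    r"entered|participat\w+|in|on)\b[^.!?]*\btrials?\b",
    re.IGNORECASE,
)


def filter_trial_posts(
    post: Post | str, investigational_lexicon: Sequence[str]
) -> tuple[bool, str]:
    """Decide whether a post stays in the corpus.

    Posts naming an investigational agent or asserting first-person trial
    participation are dropped; passing references to trials as an option
    ("my oncologist recommended I look at clinical trials") are kept.
    Returns ``(keep, reason)``.
    """
    text = post.text if isinstance(post, Post) else post
    low = text.lower()
    for drug in investigational_lexicon:
        if re.search(rf"\b{re.escape(drug.lower())}\b", low):
            return False, f"investigational drug: {drug}"
    if _PARTICIPATION_RE.search(text):
        return False, "trial participation"
    return True, ""


# ---------------------------------------------------------------------------
# Corpus-level driver
# ---------------------------------------------------------------------------

def anonymize_corpus(
    corpus: Corpus,
    salt: str,
    brand_map: BrandMap | None = None,
    lexicon: PiiLexicon | None = None,
    investigational_lexicon: Iterable[str] | None = None,
) -> tuple[Corpus, dict[str, ScrubAudit]]:
    """Full de-identification pass over a corpus.

    Order: drop trial/investigational posts, normalize brands to INNs,
    scrub PII, tokenize usernames.  Distinct users must map to distinct
    tokens; a collision is fatal.
    """
    brand_map = brand_map or BrandMap.default()
    lexicon = lexicon or PiiLexicon.default()
    inv = list(investigational_lexicon
               if investigational_lexicon is not None
               else resources.load_investigational_drugs())

    kept: list[Post] = []
    n_trial_dropped = 0
    audits: dict[str, ScrubAudit] = {}
    for p in corpus.posts:
        keep, _reason = filter_trial_posts(p, inv)
        if not keep:
            n_trial_dropped += 1
            continue
        text = map_brand_to_inn(p.text, brand_map)
        text, audit = scrub_pii(text, lexicon)
        audits[p.post_id] = audit
        kept.append(replace(p, text=text))

    token_of: dict[str, str] = {}
    tokens_seen: dict[str, str] = {}
    for user_ref in {p.user_ref for p in kept}:
        token = tokenize_username(user_ref, salt)
        if token in tokens_seen:
            raise ValueError(
                f"username token collision between {tokens_seen[token]!r} and {user_ref!r}"
            )
        tokens_seen[token] = user_ref
        token_of[user_ref] = token
    kept = [replace(p, user_ref=token_of[p.user_ref]) for p in kept]

    out = corpus.with_posts(kept, note=f"anonymize: dropped {n_trial_dropped} trial posts")
    # carry role/risk labels across the rename
    for raw, token in token_of.items():
        if raw in corpus.users:
            old = corpus.users[raw]
            u = out.users[token]
            u.role, u.risk = old.role, old.risk
            u.join_date, u.location = old.join_date, old.location
    out.provenance["trial_posts_removed"] = n_trial_dropped
    out.provenance["users_tokenized"] = len(token_of)
    return out, audits
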