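"""High-risk MDS tagging from treatment/finding surrogates.

A post is evidence of high-risk disease if it mentions a hypomethylating
agent, venetoclax, progression to AML, allogeneic/haploidentical or stem-cell
transplantation, donor lymphocyte infusion, erythropoietin failure, repeated
transfusions, intensive chemotherapy, an explicit "high-risk" description,
or a blast percentage of at least 20.  Texts are expected to be
INN-normalized first so brand names hit the generic-name lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import resources
from .corpus import Corpus, Post

__all__ = [
    "RiskMarkerLexicon",
    "RiskEvidence",
    "parse_blast_percentages",
    "detect_hr_markers",
    "classify_user_risk",
    "classify_corpus_risk",
]

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?%?|[A-Za-z']+|%")
_BLAST_WORD_RE = re.compile(r"^blasts?$|^blast$", re.IGNORECASE)


class RiskMarkerLexicon:
    """Marker categories -> surface-form lists, plus the blast rule.

    Every category must be non-empty and the blast threshold a percentage in
    (0, 100].  The explicit high-risk category deliberately does not match
    inside "very high risk", which is a distinct self-reported stratum.
    """

    def __init__(
        self,
        categories: Mapping[str, Sequence[str]],
        transfusion_words: Sequence[str] = ("transfusion", "transfusions"),
        transfusion_frequency_cues: Sequence[str] = (
            "another", "weekly", "monthly", "regular", "frequent", "multiple", "more", "again"),
        blast_threshold: float = 20.0,
        blast_token_window: int = 6,
    ):
        for name, forms in categories.items():
            if not forms:
                raise ValueError(f"marker category {name!r} is empty")
        if not (0 < blast_threshold <= 100):
            raise ValueError("blast threshold must be in (0, 100]")
        self.categories = {k: list(v) for k, v in categories.items()}
        self.transfusion_words = list(transfusion_words)
        self.transfusion_frequency_cues = [c.lower() for c in transfusion_frequency_cues]
        self.blast_threshold = float(blast_threshold)
        self.blast_token_window = int(blast_token_window)
        self._regexes: dict[str, re.Pattern] = {}
        for name, forms in self.categories.items():
            alt = "|".join(re.escape(f) for f in sorted(forms, key=len, reverse=True))
            alt = alt.replace(r"\ ", r"\s+")
            if name == "explicit_high_risk":
                self._regexes[name] = re.compile(
                    rf"(?<!very\s)(?<!very-)\b(?:{alt})\b", re.IGNORECASE)
            else:
                self._regexes[name] = re.compile(rf"\b(?:{alt})\b", re.IGNORECASE)

    @classmethod
    def default(cls) -> "RiskMarkerLexicon":
        cfg = resources.load_risk_markers()
        return cls(
            categories=cfg["categories"],
            transfusion_words=cfg["transfusion_words"],
            transfusion_frequency_cues=cfg["transfusion_frequency_cues"],
            blast_threshold=cfg["blast_threshold"],
            blast_token_window=cfg["blast_token_window"],
        )


@dataclass
class RiskEvidence:
    post_id: str
    markers: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    blast_values: list[float] = field(default_factory=list)

    @property
    def categories(self) -> set[str]:
        return {c for c, _ in self.markers}


def parse_blast_percentages(text: str, token_window: int = 6) -> list[float]:
    """Extract percentages syntactically attached to a blast mention.

    A number counts when written as ``N%``, ``N %`` or ``N percent`` within
    ``token_window`` tokens of a "blast"/"blasts"/"blast count" mention.
    Values are returned in order of appearance.
    """
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]
    blast_idx = [i for i, (tok, _) in enumerate(tokens) if _BLAST_WORD_RE.match(tok)]
    if not blast_idx:
        return []
    values: list[float] = []
    for i, (tok, _) in enumerate(tokens):
        num: float | None = None
        if re.fullmatch(r"\d+(?:\.\d+)?%", tok):
            num = float(tok[:-1])
        elif re.fullmatch(r"\d+(?:\.\d+)?", tok):
            nxt = tokens[i + 1][0].lower() if i + 1 < len(tokens) else ""
            if nxt in ("%", "percent"):
                num = float(tok)
        if num is None:
            continue
        if any(abs(i - b) <= token_window for b in blast_idx):
            values.append(num)
    return values


def detect_hr_markers(text: str, lexicon: RiskMarkerLexicon,
                      post_id: str = "") -> RiskEvidence:
    """Collect high-risk surrogate markers present in one post's text."""
    ev = RiskEvidence(post_id=post_id)
    for name, rx in lexicon._regexes.items():
        m = rx.search(text)
        if m:
            ev.markers.append((name, m.span()))

    # repeated-transfusion rule: plural form, or singular with a frequency cue
    low = text.lower()
    plural = re.search(r"\btransfusions\b", low)
    if plural:
        ev.markers.append(("multiple_transfusions", plural.span()))
    else:
        for m in re.finditer(r"\btransfusion\b", low):
            prefix_tokens = re.findall(r"[a-z']+", low[: m.start()])[-2:]
            if any(t in lexicon.transfusion_frequency_cues for t in prefix_tokens):
                ev.markers.append(("multiple_transfusions", m.span()))
                break

    ev.blast_values = parse_blast_percentages(text, lexicon.blast_token_window)
    if any(v >= lexicon.blast_threshold for v in ev.blast_values):
        ev.markers.append(("blast_threshold", (0, 0)))
    return ev


_SELF_REPORT_RES = {
    "very_high": re.compile(r"\bvery[\s-]+high[\s-]+risk\b", re.IGNORECASE),
    "low": re.compile(r"\blow(?:er)?[\s-]+risk\b", re.IGNORECASE),
    "intermediate": re.compile(r"\bintermediate(?:[\s-]+risk|[\s-]+[12]\b)", re.IGNORECASE),
}


def classify_user_risk(
    evidences: Sequence[RiskEvidence],
    texts: Sequence[str] = (),
) -> tuple[str, list[str]]:
    """Aggregate per-post evidence into one user risk label.

    Any surrogate marker makes the user ``high``; the reserved ``low`` /
    ``intermediate`` / ``very_high`` labels fire only on an explicit textual
    self-report.  Explicit lower-risk statements do not veto surrogate-derived
    high (a user may progress); such conflicts are returned for logging.
    Returns ``(label, conflicts)``.
    """
    joined = " \n ".join(texts).lower()
    self_reports = {lbl for lbl, rx in _SELF_REPORT_RES.items() if rx.search(joined)}
    has_marker = any(ev.markers for ev in evidences)

    conflicts: list[str] = []
    if "very_high" in self_reports:
        return "very_high", conflicts
    if has_marker:
        for lbl in ("low", "intermediate"):
            if lbl in self_reports:
                conflicts.append(
                    f"explicit {lbl}-risk self-report alongside high-risk surrogate markers")
        return "high", conflicts
    if "low" in self_reports:
        return "low", conflicts
    if "intermediate" in self_reports:
        return "intermediate", conflicts
    return "unknown", conflicts


def classify_corpus_risk(
    corpus: Corpus,
    lexicon: RiskMarkerLexicon | None = None,
) -> tuple[dict[str, str], dict[str, RiskEvidence]]:
    """Tag every post, aggregate per user; updates ``corpus.users``."""
    lexicon = lexicon or RiskMarkerLexicon.default()
    post_evidence = {
        p.post_id: detect_hr_markers(p.text, lexicon, post_id=p.post_id)
        for p in corpus.posts
    }
    user_risk: dict[str, str] = {}
    for user_ref, posts in corpus.posts_by_user().items():
        evs = [post_evidence[p.post_id] for p in posts]
        label, _conflicts = classify_user_risk(evs, [p.text for p in posts])
        user_risk[user_ref] = label
        if user_ref in corpus.users:
            corpus.users[user_ref].risk = label
    return user_risk, post_evidence
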