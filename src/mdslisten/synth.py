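"""Seedable synthetic forum-corpus generator with exact ground truth.

The generator emulates the population structure the analysis assumes:
a patient/caregiver/other role mix, a high-risk subcohort carrying
treatment-surrogate mentions, heavy-tailed per-user post counts with ~1%
superusers, timestamps spanning 2008-2022, and per-post injection of PII,
misspellings, duplicates, and clinical-trial mentions at configured rates.

Post text is template-based (slot-filled sentences), never free generation:
every planted marker -- role phrases, risk surrogates, theme seeds, emotion
cues, PII surface strings -- appears verbatim at a known offset, so the
ground truth is exact and downstream rule-based stages are testable without
any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from . import resources
from .corpus import Corpus, Post, Thread, User

__all__ = ["SynthConfig", "GroundTruth", "generate_corpus", "render_post", "TEMPLATES"]


EMOTION_CLASSES = ("neutral", "sadness", "joy", "surprise", "fear", "disgust", "anger")

# per-post bucket cue rates for patient/caregiver users; with ~10 posts per
# user these produce user-level union rates echoing the reported sentiment
# prevalences (concern ~78%, anxiety ~60%, ..., information seeking ~19%)
DEFAULT_BUCKET_RATES = {
    "concern": 0.14,
    "anxiety": 0.087,
    "frustration": 0.083,
    "fear": 0.083,
    "confusion": 0.065,
    "information_seeking": 0.021,
}

# source weights follow the relative post volumes of the three main forums
DEFAULT_SOURCE_WEIGHTS = {
    "mds-foundation.org": 6834,
    "marrowforums.org": 32009,
    "mdspatientsupport.uk": 2896,
}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"SynthConfig.{name} must be in [0, 1], got {value}")


@dataclass
class SynthConfig:
    """Generator parameters.

    Defaults reproduce the corpus statistics the analysis was designed
    around: ~49/42/9 patient/caregiver/other mix, ~31% high-risk users,
    ~1% superusers, a mean of ~10.5 posts per user from a regular/superuser
    mixture, and dates spanning 2008-2022.
    """

    n_users: int = 2000
    role_mix: Mapping[str, float] = field(
        default_factory=lambda: {"patient": 0.49, "caregiver": 0.42, "other": 0.09})
    hr_fraction: float = 0.31
    low_risk_fraction: float = 0.05
    intermediate_risk_fraction: float = 0.03
    superuser_fraction: float = 0.01
    mean_posts_regular: float = 7.5
    mean_posts_superuser: float = 300.0
    date_range: tuple[date, date] = (date(2008, 1, 1), date(2022, 12, 31))
    pii_rate: float = 0.05
    misspell_rate: float = 0.10
    duplicate_rate: float = 0.02
    trial_mention_rate: float = 0.01
    emotion_mix: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 0.37, "sadness": 0.22, "joy": 0.20,
                                 "surprise": 0.13, "fear": 0.04, "disgust": 0.02,
                                 "anger": 0.02})
    bucket_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BUCKET_RATES))
    source_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_WEIGHTS))
    new_thread_prob: float = 0.13
    median_active_days: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 0:
            raise ValueError(f"SynthConfig.n_users must be >= 0, got {self.n_users}")
        for name in ("hr_fraction", "low_risk_fraction", "intermediate_risk_fraction",
                     "superuser_fraction", "pii_rate", "misspell_rate",
                     "duplicate_rate", "trial_mention_rate", "new_thread_prob"):
            _check_prob(name, getattr(self, name))
        for name, mix in (("role_mix", self.role_mix), ("emotion_mix", self.emotion_mix)):
            for k, v in mix.items():
                _check_prob(f"{name}[{k!r}]", v)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"SynthConfig.{name} must sum to 1, got {sum(mix.values())}")
        for k, v in self.bucket_rates.items():
            _check_prob(f"bucket_rates[{k!r}]", v)
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("SynthConfig.date_range start must be <= end")
        if self.mean_posts_regular < 1 or self.mean_posts_superuser < 1:
            raise ValueError("SynthConfig mean post counts must be >= 1")


@dataclass(frozen=True)
class PiiSpan:
    start: int
    end: int
    category: str  # NAME, PROVIDER, EMAIL, PHONE, MANUFACTURER
    surface: str


@dataclass
class GroundTruth:
    """Planted labels for every generated user and post."""

    user_role: dict[str, str] = field(default_factory=dict)
    user_risk: dict[str, str] = field(default_factory=dict)
    superusers: set[str] = field(default_factory=set)
    post_emotions: dict[str, frozenset[str]] = field(default_factory=dict)
    post_buckets: dict[str, frozenset[str]] = field(default_factory=dict)
    post_themes: dict[str, frozenset[str]] = field(default_factory=dict)
    pii_spans: dict[str, list[PiiSpan]] = field(default_factory=dict)
    trial_flag: dict[str, bool] = field(default_factory=dict)
    duplicate_of: dict[str, str] = field(default_factory=dict)
    misspellings: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def pii_surfaces(self) -> set[str]:
        return {s.surface for spans in self.pii_spans.values() for s in spans}


# ---------------------------------------------------------------------------
# Template text
# ---------------------------------------------------------------------------

OPENERS = (
    "Hello everyone, just checking in.",
    "Back again with an update from our side.",
    "It has been a long week here.",
    "Writing this from the waiting room.",
    "Quick update for the group.",
    "First time posting in a while.",
)

CLOSERS = (
    "Thanks for reading and take care.",
    "Grateful for this group.",
    "Will post more when we know more.",
    "Thank you all for listening.",
    "Wishing everyone a calm week.",
)

NEWS_SENTENCES = (
    "Sharing a news article I found about the disease.",
    "This press release covers the new data.",
    "According to the article, researchers announced new findings.",
)

# carrier templates used by render_post: each embeds one marker verbatim once
TEMPLATES: dict[str, tuple[str, ...]] = {
    "statement": (
        "{marker}.",
        "{marker}, so that is where things stand.",
        "The short version is that {marker}.",
        "To be honest, {marker} and we are taking it day by day.",
    ),
    "mention": (
        "We talked about {marker} at the last visit.",
        "Lately a lot of our time goes to {marker}.",
        "The conversation keeps coming back to {marker}.",
        "I spent the morning dealing with {marker}.",
    ),
    "feeling": (
        "I would say {marker} describes how it feels.",
        "Mostly I have been feeling {marker} about all of it.",
        "If I am honest, {marker} is the word for this week.",
    ),
}


def render_post(template_id: str, markers: Sequence[str], rng: np.random.Generator) -> str:
    """Render marker strings through a named carrier template family.

    Each requested marker appears verbatim exactly once; the surrounding
    filler is drawn deterministically from ``rng``.
    """
    if template_id not in TEMPLATES:
        raise ValueError(f"unknown template {template_id!r}")
    carriers = TEMPLATES[template_id]
    parts = []
    for marker in markers:
        carrier = carriers[int(rng.integers(len(carriers)))]
        parts.append(carrier.format(marker=marker))
    return " ".join(parts)


# risk-surrogate surface realizations; the venetoclax category is sometimes
# realized by its brand name to exercise brand->INN normalization upstream
_HR_SURFACES = {
    "hypomethylating_agent": ("I started azacitidine last month",
                              "they put me on decitabine this cycle"),
    "venetoclax": ("venetoclax was added to the plan",
                   "Venclexta was added to the plan"),
    "aml_progression": ("the disease progressed to AML",),
    "transplant": ("we are preparing for a stem cell transplant",
                   "the team scheduled an allogeneic transplant"),
    "donor_lymphocyte_infusion": ("a donor lymphocyte infusion is planned",),
    "erythropoietin_failure": ("the epo stopped working for the anemia",),
    "multiple_transfusions": ("the weekly transfusions continue",),
    "intensive_chemotherapy": ("they recommended intensive chemotherapy",),
    "explicit_high_risk": ("they said this is high-risk disease",),
    "blast_threshold": None,  # numeric, built separately
}

_LOW_RISK_STATEMENTS = {
    "low": "they told us it is low-risk MDS for now",
    "intermediate": "the score puts it at intermediate risk",
}

# misspelled token -> correct form; each misspelling is Damerau distance 1
# from its correction and absent from the bundled dictionary
MISSPELLING_SENTENCES = (
    ("I hope to recieve the results soon.", "recieve", "receive"),
    ("Our docter was very kind about it.", "docter", "doctor"),
    ("I have been so tierd lately.", "tierd", "tired"),
    ("They checked the bone marow again.", "marow", "marrow"),
    ("The next transfusoin is on Friday.", "transfusoin", "transfusion"),
    ("We have an apointment on Monday.", "apointment", "appointment"),
)

_TRIAL_SENTENCE = "I decided to start a clinical trial with a new drug called sabatolimab."

_HANDLE_WORDS = ("bluebird", "hopeful", "runner", "gardener", "seastar", "walker",
                 "mountain", "quilter", "reader", "sailor", "pine", "willow",
                 "harbor", "meadow", "lantern", "sparrow")

_LOCATIONS = ("United States", "United Kingdom", "Canada")


class _TextBuilder:
    """Accumulates sentences while tracking character spans of PII."""

    def __init__(self):
        self._parts: list[str] = []
        self._len = 0
        self.pii: list[PiiSpan] = []

    def add(self, sentence: str, pii: Sequence[tuple[str, str]] = ()) -> None:
        offset = self._len + (1 if self._parts else 0)  # joining space
        for category, surface in pii:
            local = sentence.find(surface)
            if local < 0:
                raise AssertionError(f"pii surface {surface!r} not in sentence")
            self.pii.append(PiiSpan(offset + local, offset + local + len(surface),
                                    category, surface))
        self._parts.append(sentence)
        self._len = offset + len(sentence)

    def text(self) -> str:
        return " ".join(self._parts)


def _sample_posts_dates(rng: np.random.Generator, n: int, cfg: SynthConfig,
                        superuser: bool) -> list[date]:
    start_ord = cfg.date_range[0].toordinal()
    end_ord = cfg.date_range[1].toordinal()
    total = end_ord - start_ord
    if superuser:
        span = min(total, int(rng.lognormal(math.log(800), 0.5)))
    else:
        # median ~10 days, heavy right tail reaching past 1000 days
        span = min(total, int(rng.lognormal(math.log(cfg.median_active_days), 1.6)))
    first = start_ord + int(rng.integers(0, max(1, total - span + 1)))
    offsets = np.sort(rng.integers(0, span + 1, size=n))
    return [date.fromordinal(first + int(o)) for o in offsets]


def generate_corpus(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus and its ground truth; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gt = GroundTruth()

    hierarchy_cfg = resources.load_theme_hierarchy_config()
    theme_seeds: dict[str, list[str]] = {}
    for name, node in hierarchy_cfg["roots"].items():
        theme_seeds[name] = list(node["seeds"])
    for name, node in hierarchy_cfg["subthemes"].items():
        theme_seeds[name] = list(node["seeds"])
    theme_names = sorted(theme_seeds)

    cues = resources.load_emotion_cues()
    emotion_cues = {k: list(v) for k, v in cues["classes"].items()}
    bucket_cues = {k: list(v) for k, v in cues["buckets"].items()}

    role_cfg = resources.load_role_phrases()
    patient_phrases = list(role_cfg["patient"])
    caregiver_patterns = list(role_cfg["caregiver_patterns"])
    kin_nouns = list(role_cfg["kin_nouns"])

    given = resources.load_given_names()
    sur = resources.load_surnames()
    manufacturers = resources.load_manufacturers()

    roles = list(config.role_mix)
    role_p = np.array([config.role_mix[r] for r in roles], dtype=float)
    emo_classes = [c for c in EMOTION_CLASSES if c in config.emotion_mix]
    emo_p = np.array([config.emotion_mix[c] for c in emo_classes], dtype=float)
    emo_p = emo_p / emo_p.sum()
    sources = sorted(config.source_weights)
    src_p = np.array([config.source_weights[s] for s in sources], dtype=float)
    src_p = src_p / src_p.sum()

    posts: list[Post] = []
    users: dict[str, User] = {}
    threads: dict[str, Thread] = {}
    threads_by_source: dict[str, list[str]] = {s: [] for s in sources}
    post_counter = 0
    thread_counter = 0

    def new_thread(source: str, day: date) -> str:
        nonlocal thread_counter
        tid = f"t{thread_counter:06d}"
        thread_counter += 1
        threads[tid] = Thread(thread_id=tid, title=f"Thread {tid}", source=source)
        threads_by_source[source].append(tid)
        return tid

    def role_marker_sentence(role: str) -> str:
        if role == "patient":
            phrase = patient_phrases[int(rng.integers(len(patient_phrases)))]
        else:
            pattern = caregiver_patterns[int(rng.integers(len(caregiver_patterns)))]
            phrase = pattern.replace("{kin}", kin_nouns[int(rng.integers(len(kin_nouns)))])
        return render_post("statement", [phrase], rng)

    def pii_sentence() -> tuple[str, list[tuple[str, str]]]:
        kind = int(rng.integers(5))
        if kind == 0:  # person name
            surface = f"{given[int(rng.integers(len(given)))]} {sur[int(rng.integers(len(sur)))]}"
            return f"Please thank {surface} for the ride last week.", [("NAME", surface)]
        if kind == 1:  # provider
            surface = f"Dr {sur[int(rng.integers(len(sur)))]}"
            return f"We met {surface} on Tuesday.", [("PROVIDER", surface)]
        if kind == 2:  # email
            surface = (f"{given[int(rng.integers(len(given)))].lower()}"
                       f"{int(rng.integers(10, 99))}@example.com")
            return f"You can write to me at {surface} any time.", [("EMAIL", surface)]
        if kind == 3:  # phone
            surface = (f"{int(rng.integers(200, 999))}-{int(rng.integers(200, 999))}-"
                       f"{int(rng.integers(1000, 9999))}")
            return f"Call {surface} if you are in the area.", [("PHONE", surface)]
        surface = manufacturers[int(rng.integers(len(manufacturers)))]
        return f"The pharmacist said {surface} makes this one.", [("MANUFACTURER", surface)]

    for uidx in range(config.n_users):
        handle = (f"{_HANDLE_WORDS[int(rng.integers(len(_HANDLE_WORDS)))]}"
                  f"{uidx:04d}")
        role = roles[int(rng.choice(len(roles), p=role_p))]
        if role == "other":
            risk = "unknown"
        elif rng.random() < config.hr_fraction:
            risk = "high"
        elif rng.random() < config.low_risk_fraction:
            risk = "low"
        elif rng.random() < config.intermediate_risk_fraction:
            risk = "intermediate"
        else:
            risk = "unknown"
        superuser = bool(rng.random() < config.superuser_fraction)
        mean = config.mean_posts_superuser if superuser else config.mean_posts_regular
        n_posts = 1 + int(rng.poisson(mean - 1))
        dates = _sample_posts_dates(rng, n_posts, config, superuser)
        source = sources[int(rng.choice(len(sources), p=src_p))]
        location = _LOCATIONS[int(rng.integers(len(_LOCATIONS)))]

        gt.user_role[handle] = role
        gt.user_risk[handle] = risk
        if superuser:
            gt.superusers.add(handle)
        users[handle] = User(user_ref=handle, join_date=dates[0], location=location)

        if risk == "high":
            n_marker = max(1, int(math.ceil(0.3 * n_posts)))
            marker_posts = set(rng.choice(n_posts, size=min(n_marker, n_posts),
                                          replace=False).tolist())
        else:
            marker_posts = set()
        low_report_post = int(rng.integers(n_posts)) if risk in ("low", "intermediate") else -1

        user_posts: list[tuple[Post, dict]] = []
        for pidx in range(n_posts):
            builder = _TextBuilder()
            builder.add(OPENERS[int(rng.integers(len(OPENERS)))])

            labels: dict = {"emotions": set(), "buckets": set(), "themes": set(),
                            "trial": False, "misspellings": []}

            if role in ("patient", "caregiver"):
                builder.add(role_marker_sentence(role))
            else:
                if rng.random() < 0.5:
                    builder.add(NEWS_SENTENCES[int(rng.integers(len(NEWS_SENTENCES)))])

            n_themes = 1 + int(rng.integers(3))
            picked = rng.choice(len(theme_names), size=min(n_themes, len(theme_names)),
                                replace=False)
            for ti in picked:
                node = theme_names[int(ti)]
                seed = theme_seeds[node][int(rng.integers(len(theme_seeds[node])))]
                builder.add(render_post("mention", [seed], rng))
                labels["themes"].add(node)

            emo = emo_classes[int(rng.choice(len(emo_classes), p=emo_p))]
            if emo != "neutral":
                cue = emotion_cues[emo][int(rng.integers(len(emotion_cues[emo])))]
                builder.add(render_post("feeling", [cue], rng))
                labels["emotions"].add(emo)
            if rng.random() < 0.1:
                extra = emo_classes[1:][int(rng.integers(len(emo_classes) - 1))]
                if extra not in labels["emotions"]:
                    cue = emotion_cues[extra][int(rng.integers(len(emotion_cues[extra])))]
                    builder.add(render_post("feeling", [cue], rng))
                    labels["emotions"].add(extra)

            if role in ("patient", "caregiver"):
                for bucket, rate in config.bucket_rates.items():
                    if rng.random() < rate:
                        cue = bucket_cues[bucket][int(rng.integers(len(bucket_cues[bucket])))]
                        builder.add(render_post("feeling", [cue], rng))
                        labels["buckets"].add(bucket)

            has_hr_marker = pidx in marker_posts
            if has_hr_marker:
                cat = sorted(_HR_SURFACES)[int(rng.integers(len(_HR_SURFACES)))]
                if _HR_SURFACES[cat] is None:  # blast percentage >= threshold
                    value = int(rng.integers(20, 36))
                    builder.add(f"The blast count came back at {value}% this time.")
                else:
                    surfaces = _HR_SURFACES[cat]
                    builder.add(render_post(
                        "statement", [surfaces[int(rng.integers(len(surfaces)))]], rng))
            if pidx == low_report_post:
                builder.add(render_post("statement", [_LOW_RISK_STATEMENTS[risk]], rng))

            pii: list[tuple[str, str]] = []
            if rng.random() < config.pii_rate:
                sentence, pii = pii_sentence()
                builder.add(sentence, pii)

            if (not has_hr_marker) and rng.random() < config.trial_mention_rate:
                builder.add(_TRIAL_SENTENCE)
                labels["trial"] = True

            if rng.random() < config.misspell_rate:
                sent, mis, corr = MISSPELLING_SENTENCES[
                    int(rng.integers(len(MISSPELLING_SENTENCES)))]
                builder.add(sent)
                labels["misspellings"].append((mis, corr))

            builder.add(CLOSERS[int(rng.integers(len(CLOSERS)))])

            day = dates[pidx]
            if not threads_by_source[source] or rng.random() < config.new_thread_prob:
                tid = new_thread(source, day)
            else:
                pool = threads_by_source[source]
                tid = pool[int(rng.integers(len(pool)))]
            post_id = f"p{post_counter:06d}"
            post_counter += 1
            post = Post(post_id=post_id, thread_id=tid, user_ref=handle,
                        timestamp=day, source=source, text=builder.text())
            labels["pii"] = builder.pii
            user_posts.append((post, labels))

        # duplicates: re-post of an earlier text by the same user, later date
        extra: list[tuple[Post, dict]] = []
        for post, labels in user_posts:
            if rng.random() < config.duplicate_rate:
                dup_id = f"p{post_counter:06d}"
                post_counter += 1
                delta = int(rng.integers(1, 31))
                day = min(post.timestamp + timedelta(days=delta), config.date_range[1])
                dup = Post(post_id=dup_id, thread_id=post.thread_id,
                           user_ref=handle, timestamp=day, source=source,
                           text=post.text)
                gt.duplicate_of[dup_id] = post.post_id
                extra.append((dup, labels))
        user_posts.extend(extra)

        for post, labels in user_posts:
            # the fear bucket and the fear emotion share one cue lexicon, so
            # planting either implies both labels
            emotions = set(labels["emotions"])
            buckets = set(labels["buckets"])
            if "fear" in buckets:
                emotions.add("fear")
            if "fear" in emotions:
                buckets.add("fear")
            gt.post_emotions[post.post_id] = frozenset(emotions or {"neutral"})
            gt.post_buckets[post.post_id] = frozenset(buckets)
            gt.post_themes[post.post_id] = frozenset(labels["themes"])
            gt.pii_spans[post.post_id] = list(labels["pii"])
            gt.trial_flag[post.post_id] = labels["trial"]
            gt.misspellings[post.post_id] = list(labels["misspellings"])
            posts.append(post)

    # finalize thread post counts
    for tid in threads:
        threads[tid].n_posts = 0
    for p in posts:
        threads[p.thread_id].n_posts += 1
    threads = {tid: t for tid, t in threads.items() if t.n_posts > 0}

    corpus = Corpus(posts=posts, threads=threads, users=users,
                    study_window=config.date_range,
                    provenance={"generator": "mdslisten.synth",
                                "seed": config.seed,
                                "n_users": config.n_users,
                                "sources": sources,
                                "log": []})
    return corpus, gt


def write_ground_truth(gt: GroundTruth, out_dir) -> None:
    """Write the ground-truth sidecar tables (per-user and per-post CSVs)."""
    import csv
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "ground_truth_users.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["user_ref", "role", "risk", "superuser"])
        for user in sorted(gt.user_role):
            w.writerow([user, gt.user_role[user], gt.user_risk[user],
                        int(user in gt.superusers)])
    with (out / "ground_truth_posts.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["post_id", "emotions", "buckets", "themes", "trial",
                    "duplicate_of", "pii_spans", "misspellings"])
        for pid in sorted(gt.post_emotions):
            spans = [[s.start, s.end, s.category, s.surface]
                     for s in gt.pii_spans.get(pid, [])]
            w.writerow([
                pid,
                ";".join(sorted(gt.post_emotions[pid])),
                ";".join(sorted(gt.post_buckets[pid])),
                ";".join(sorted(gt.post_themes[pid])),
                int(gt.trial_flag.get(pid, False)),
                gt.duplicate_of.get(pid, ""),
                json.dumps(spans),
                json.dumps(gt.misspellings.get(pid, [])),
            ])
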