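"""End-to-end pipeline: load -> clean/dedup/exclude -> anonymize -> roles ->
risk -> themes -> sentiment -> engagement/saturation/temporal -> report.

Every numeric constant of the analysis (80% role majority, blast threshold,
prevalence threshold, superuser fraction, pandemic split dates) is surfaced
as a named configuration field.  The run is fully deterministic for a fixed
config and seed, and every stage's input/output/removed counts are conserved
in the report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import resources
from .anonymize import anonymize_corpus
from .corpus import (DEFAULT_STUDY_WINDOW, Corpus, ExclusionRules, SpellDictionary,
                     apply_exclusion_filters, clean_corpus, deduplicate, load_corpus)
from .engagement import (covid_split, detect_superusers, engagement_metrics,
                         normalize_superuser_influence, saturation_analysis)
from .risk import RiskMarkerLexicon, classify_corpus_risk
from .roles import RolePhraseLexicon, classify_corpus_roles
from .sentiment import (SubSentimentMap, aggregate_prevalence, classify_buckets,
                        classify_emotions, map_subsentiments, user_label_union)
from .themes import (ThemeHierarchy, assign_corpus_themes, build_theme_network,
                     categorize_theme, score_prevalence)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "export_summary", "total_row"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their analysis defaults."""

    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW
    salt: str = "mdslisten-default-salt"
    role_majority_threshold: float = 0.8
    role_confidence_threshold: float = 0.9
    blast_threshold: float = 20.0
    prevalence_threshold_fraction: float = 0.05  # of discussions => major theme
    emotion_cutoff: float = 0.5
    superuser_fraction: float = 0.01
    superuser_cap: int = 1
    saturation_batch_size: int = 500
    saturation_lookahead: int = 3
    max_edit_distance: int = 1
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not (0 < self.role_majority_threshold <= 1):
            raise ValueError("role_majority_threshold must be in (0, 1]")
        if not (0 < self.blast_threshold <= 100):
            raise ValueError("blast_threshold must be in (0, 100]")
        if not (0 <= self.prevalence_threshold_fraction <= 1):
            raise ValueError("prevalence_threshold_fraction must be in [0, 1]")
        if not (0 < self.superuser_fraction < 1):
            raise ValueError("superuser_fraction must be in (0, 1)")
        if self.superuser_cap < 1 or self.saturation_batch_size < 1:
            raise ValueError("superuser_cap and saturation_batch_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "study_window" in raw:
            lo, hi = raw["study_window"]
            raw["study_window"] = (date.fromisoformat(str(lo)), date.fromisoformat(str(hi)))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int

    @property
    def removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class RunReport:
    config: dict
    stage_counts: list[StageCount] = field(default_factory=list)
    corpus_summary: list[dict] = field(default_factory=list)  # per-source + Total
    cohort_sizes: dict = field(default_factory=dict)
    role_counts: dict = field(default_factory=dict)
    risk_counts: dict = field(default_factory=dict)
    sentiment_tables: dict = field(default_factory=dict)  # cohort -> rows
    theme_prevalence: list[dict] = field(default_factory=list)
    network_edges: list[dict] = field(default_factory=list)
    saturation: dict = field(default_factory=dict)
    covid_counts: dict = field(default_factory=dict)
    engagement_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stage_counts": [
                {"stage": s.stage, "in": s.n_in, "out": s.n_out, "removed": s.removed}
                for s in self.stage_counts
            ],
            "corpus_summary": self.corpus_summary,
            "cohort_sizes": self.cohort_sizes,
            "role_counts": self.role_counts,
            "risk_counts": self.risk_counts,
            "sentiment_tables": self.sentiment_tables,
            "theme_prevalence": self.theme_prevalence,
            "network_edges": self.network_edges,
            "saturation": self.saturation,
            "covid_counts": self.covid_counts,
            "engagement_summary": self.engagement_summary,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["study_window"] = [cfg.study_window[0].isoformat(), cfg.study_window[1].isoformat()]
    d.pop("salt", None)  # never reported or logged
    return d


def total_row(rows: list[dict]) -> dict:
    """Total row of a per-source summary table: independent column sums."""
    return {
        "source": "Total",
        "posts": sum(r["posts"] for r in rows),
        "threads": sum(r["threads"] for r in rows),
        "users": sum(r["users"] for r in rows),
    }


def _source_summary(corpus: Corpus) -> list[dict]:
    rows = []
    by_source: dict[str, dict] = {}
    for p in corpus.posts:
        s = by_source.setdefault(p.source, {"posts": 0, "threads": set(), "users": set()})
        s["posts"] += 1
        s["threads"].add(p.thread_id)
        s["users"].add(p.user_ref)
    for source in sorted(by_source):
        s = by_source[source]
        rows.append({"source": source, "posts": s["posts"],
                     "threads": len(s["threads"]), "users": len(s["users"])})
    rows.append(total_row(rows))
    return rows


def run_pipeline(
    config: PipelineConfig,
    corpus_path: str | Path | None = None,
    corpus: Corpus | None = None,
) -> tuple[RunReport, Corpus]:
    """Run every stage in order and return the report plus the final corpus.

    Exactly one of ``corpus_path`` / ``corpus`` must be given.  Any stage
    failure propagates as an exception tagged with the stage name.
    """
    config.validate()
    if (corpus_path is None) == (corpus is None):
        raise ValueError("provide exactly one of corpus_path or corpus")

    report = RunReport(config=_config_dict(config))

    def stage(name: str, n_in: int, n_out: int) -> None:
        report.stage_counts.append(StageCount(name, n_in, n_out))

    try:
        if corpus_path is not None:
            corpus = load_corpus(corpus_path, study_window=config.study_window)
        else:
            corpus = Corpus(list(corpus.posts), dict(corpus.threads), dict(corpus.users),
                            config.study_window, dict(corpus.provenance))
        stage("load", corpus.n_posts, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    try:
        n = corpus.n_posts
        corpus = deduplicate(corpus)
        stage("deduplicate", n, corpus.n_posts)

        n = corpus.n_posts
        dictionary = SpellDictionary.from_file(resources.wordlist_path())
        corpus = clean_corpus(corpus, dictionary, config.max_edit_distance)
        stage("clean", n, corpus.n_posts)

        n = corpus.n_posts
        corpus = apply_exclusion_filters(corpus, ExclusionRules(window=config.study_window))
        stage("exclude", n, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[clean] {exc}") from exc

    try:
        n = corpus.n_posts
        corpus, _audits = anonymize_corpus(corpus, salt=config.salt)
        stage("anonymize", n, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[anonymize] {exc}") from exc

    try:
        role_decisions, _post_roles = classify_corpus_roles(
            corpus,
            RolePhraseLexicon.default(),
            majority_threshold=config.role_majority_threshold,
            confidence_threshold=config.role_confidence_threshold,
        )
        stage("roles", corpus.n_posts, corpus.n_posts)
        report.role_counts = {
            r: sum(1 for d in role_decisions.values() if d.role == r)
            for r in ("patient", "caregiver", "unknown")
        }
    except Exception as exc:
        raise RuntimeError(f"[roles] {exc}") from exc

    try:
        risk_lexicon = RiskMarkerLexicon.default()
        risk_lexicon.blast_threshold = config.blast_threshold
        user_risk, _evidence = classify_corpus_risk(corpus, risk_lexicon)
        stage("risk", corpus.n_posts, corpus.n_posts)
        report.risk_counts = {
            r: sum(1 for v in user_risk.values() if v == r)
            for r in ("high", "very_high", "intermediate", "low", "unknown")
        }
    except Exception as exc:
        raise RuntimeError(f"[risk] {exc}") from exc

    try:
        hierarchy = ThemeHierarchy.default()
        assignments = assign_corpus_themes(corpus, hierarchy)
        theme_labels = {pid: sorted(a.theme_set) for pid, a in assignments.items()}
        discussion_of = {p.post_id: p.thread_id for p in corpus.posts}

        profiles, eng_summary = engagement_metrics(corpus)
        if profiles:
            detect_superusers(profiles, config.superuser_fraction)
        weights = normalize_superuser_influence(corpus, profiles, config.superuser_cap)

        prevalence = score_prevalence(theme_labels, discussion_of, weights)
        n_discussions = len(set(discussion_of.values()))
        threshold = max(1, math.ceil(
            config.prevalence_threshold_fraction * n_discussions))
        major_themes = set()
        for theme in sorted(hierarchy.nodes):
            prev = prevalence.get(theme, 0)
            size, actionability = categorize_theme(
                theme, prev, threshold, hierarchy.is_actionable(theme))
            if size == "major":
                major_themes.add(theme)
            report.theme_prevalence.append(
                {"theme": theme, "prevalence": prev, "size": size,
                 "actionability": actionability})
        network = build_theme_network(theme_labels, discussion_of, weights)
        report.network_edges = [
            {"source": a, "target": b, "weight": int(d["weight"])}
            for a, b, d in sorted(network.edges(data=True))
        ]
        stage("themes", corpus.n_posts, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[themes] {exc}") from exc

    try:
        post_emotions = {p.post_id: classify_emotions(p, cutoff=config.emotion_cutoff).labels
                         for p in corpus.posts}
        post_buckets = {p.post_id: classify_buckets(p, cutoff=config.emotion_cutoff)
                        for p in corpus.posts}
        sub_map = SubSentimentMap()
        _attributions = {
            pid: map_subsentiments(post_buckets[pid], theme_labels[pid], sub_map)
            for pid in post_buckets
        }
        by_user = corpus.posts_by_user()
        user_emotions = user_label_union(post_emotions, by_user, weights)
        user_buckets = user_label_union(post_buckets, by_user, weights)

        hr_users = sorted(u for u, usr in corpus.users.items()
                          if usr.risk in ("high", "very_high"))
        hr_patients = sorted(u for u in hr_users if corpus.users[u].role == "patient")
        hr_caregivers = sorted(u for u in hr_users if corpus.users[u].role == "caregiver")
        report.cohort_sizes = {"hr_users": len(hr_users), "hr_patients": len(hr_patients),
                               "hr_caregivers": len(hr_caregivers),
                               "all_users": corpus.n_users}
        for name, cohort in (("hr_users", hr_users), ("hr_patients", hr_patients),
                             ("hr_caregivers", hr_caregivers)):
            if not cohort:
                report.sentiment_tables[name] = []
                continue
            table = aggregate_prevalence(user_buckets, cohort, cohort_name=name)
            report.sentiment_tables[name] = [
                {"label": r.label, "n": r.n, "pct": r.pct} for r in table.rows
            ]
        report.sentiment_tables["emotions_all_users"] = (
            [] if not corpus.users else [
                {"label": r.label, "n": r.n, "pct": r.pct}
                for r in aggregate_prevalence(
                    user_emotions, sorted(corpus.users), cohort_name="all_users").rows
            ])
        stage("sentiment", corpus.n_posts, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[sentiment] {exc}") from exc

    try:
        report.engagement_summary = eng_summary
        report.engagement_summary["n_superusers"] = sum(
            1 for p in profiles.values() if p.is_superuser)
        curve = saturation_analysis(
            corpus.posts, theme_labels, major_themes,
            batch_size=config.saturation_batch_size,
            lookahead=config.saturation_lookahead)
        report.saturation = {
            "batch_size": curve.batch_size,
            "lookahead": curve.lookahead,
            "cumulative": curve.cumulative,
            "saturation_index": curve.saturation_index,
            "n_significant_themes": len(major_themes),
        }
        split = covid_split(corpus.posts)
        report.covid_counts = {k: len(v) for k, v in split.items()}
        stage("temporal", corpus.n_posts, corpus.n_posts)
    except Exception as exc:
        raise RuntimeError(f"[temporal] {exc}") from exc

    report.corpus_summary = _source_summary(corpus)

    if config.output_dir:
        export_summary(report, config.output_dir, network=network)
    return report, corpus


def export_summary(report: RunReport, out_dir: str | Path,
                   network: nx.Graph | None = None) -> dict[str, Path]:
    """Write all report tables as delimited files plus one JSON run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = path

    write_csv("corpus_summary.csv", pd.DataFrame(
        report.corpus_summary, columns=["source", "posts", "threads", "users"]))
    sentiment_rows = [
        {"cohort": cohort, **row}
        for cohort, rows in sorted(report.sentiment_tables.items())
        for row in rows
    ]
    write_csv("sentiment_prevalence.csv", pd.DataFrame(
        sentiment_rows, columns=["cohort", "label", "n", "pct"]))
    write_csv("theme_prevalence.csv", pd.DataFrame(
        report.theme_prevalence, columns=["theme", "prevalence", "size", "actionability"]))
    write_csv("network_edges.csv", pd.DataFrame(
        report.network_edges, columns=["source", "target", "weight"]))
    write_csv("saturation_curve.csv", pd.DataFrame(
        {"batch": range(1, len(report.saturation.get("cumulative", [])) + 1),
         "cumulative_significant_themes": report.saturation.get("cumulative", [])}))
    write_csv("covid_split.csv", pd.DataFrame(
        [report.covid_counts], columns=["pre", "post", "excluded"])
        if report.covid_counts else pd.DataFrame(columns=["pre", "post", "excluded"]))

    if network is not None:
        gml = out / "theme_network.graphml"
        nx.write_graphml(network, gml)
        paths["theme_network.graphml"] = gml

    rpt = out / "run_report.json"
    rpt.write_text(report.to_json(), encoding="utf-8")
    paths["run_report.json"] = rpt
    return paths
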