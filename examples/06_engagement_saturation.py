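"""Engagement spans, superuser capping, thematic saturation, COVID split."""

from mdslisten import (SynthConfig, assign_corpus_themes, covid_split,
                       detect_superusers, engagement_metrics, generate_corpus,
                       normalize_superuser_influence, saturation_analysis,
                       score_prevalence)

corpus, _ = generate_corpus(SynthConfig(n_users=400, seed=8))

profiles, summary = engagement_metrics(corpus)
print("activity span (days): min {min_span_days}, median {median_span_days}, "
      "max {max_span_days}".format(**summary))
print(f"users disengaging within 2 days: {summary['retention_2day_fraction']:.0%}")

detect_superusers(profiles, fraction=0.01)
supers = [p for p in profiles.values() if p.is_superuser]
print(f"superusers (top ~1% by posts): {len(supers)}, "
      f"largest={max(p.post_count for p in supers)} posts")

# cap superuser influence at 1 post per discussion before aggregation
weights = normalize_superuser_influence(corpus, profiles, cap=1)
assignments = {pid: a.theme_set for pid, a in assign_corpus_themes(corpus).items()}
discussion_of = {p.post_id: p.thread_id for p in corpus.posts}
before = score_prevalence(assignments, discussion_of)
after = score_prevalence(assignments, discussion_of, weights)
changed = {t: (before[t], after[t]) for t in before if after.get(t, 0) != before[t]}
print(f"themes whose prevalence drops after capping: {len(changed)}")

# saturation: batch-wise discovery of significant themes in post order
n_disc = len(set(discussion_of.values()))
significant = {t for t, v in before.items() if v >= 0.05 * n_disc}
curve = saturation_analysis(corpus.posts, assignments, significant,
                            batch_size=500, lookahead=3)
print(f"saturation: {len(significant)} significant themes, "
      f"cumulative per batch {curve.cumulative}, index={curve.saturation_index}")

split = covid_split(corpus.posts)
print("COVID split:", {k: len(v) for k, v in split.items()},
      "(pre = Jan 2018 - Feb 2020, post = Mar 2020 onward)")
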