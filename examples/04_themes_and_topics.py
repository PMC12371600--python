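"""Theme assignment, latent topics, prevalence, and the co-mention network.

Top-down: posts are mapped to the five root themes / subthemes and seven
broad categories by seeded keywords.  Bottom-up: LDA or clustering uncovers
latent topics that a reviewer can fold into the hierarchy.  Prevalence is
counted over unique discussions (threads).
"""

from mdslisten import (SynthConfig, ThemeHierarchy, assign_corpus_themes,
                       build_theme_network, categorize_theme, fit_latent_topics,
                       generate_corpus, score_prevalence)

corpus, _ = generate_corpus(SynthConfig(n_users=150, seed=3))
hierarchy = ThemeHierarchy.default()

assignments = assign_corpus_themes(corpus, hierarchy)
theme_labels = {pid: a.theme_set for pid, a in assignments.items()}
discussion_of = {p.post_id: p.thread_id for p in corpus.posts}

prevalence = score_prevalence(theme_labels, discussion_of)
n_disc = len(set(discussion_of.values()))
threshold = max(1, round(0.05 * n_disc))  # major = mentioned in >=5% of discussions
print(f"{n_disc} discussions; major-theme threshold = {threshold}\n")
print("theme                                   prevalence  size    actionable")
for theme, prev in sorted(prevalence.items(), key=lambda kv: -kv[1])[:8]:
    size, act = categorize_theme(theme, prev, threshold, hierarchy.is_actionable(theme))
    print(f"{theme:40}{prev:9}  {size:6}  {act}")

network = build_theme_network(theme_labels, discussion_of)
top = sorted(network.edges(data=True), key=lambda e: -e[2]["weight"])[:3]
print("\nstrongest co-mentions (discussions sharing both themes):")
for a, b, d in top:
    print(f"  {a} -- {b}: {d['weight']}")

texts = [p.text for p in corpus.posts]
model = fit_latent_topics(texts, method="lda", k=5, seed=0)
print("\nlatent topics (top terms):")
for tid in model.topic_ids:
    print(f"  topic {tid}: {', '.join(model.topic_terms[tid][:6])}")
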