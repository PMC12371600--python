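"""Emotion classification and the high-risk sentiment prevalence table.

Posts get multilabel emotions from the seven-way scheme; high-risk
sub-sentiment buckets (concern, anxiety, frustration, fear, confusion,
information seeking) are attributed to the themes of the post.  Prevalence
is user-denominated: a user expresses a sentiment if any of their posts does.
"""

from mdslisten import (SynthConfig, aggregate_prevalence, anonymize_corpus,
                       assign_corpus_themes, classify_buckets, classify_corpus_risk,
                       classify_emotions, generate_corpus, map_subsentiments,
                       user_label_union)

corpus, _ = generate_corpus(SynthConfig(n_users=400, seed=12))
anon, _ = anonymize_corpus(corpus, salt="demo")
user_risk, _ = classify_corpus_risk(anon)

post = "I am so confused by the diagnosis and terrified of what comes next."
print("example post:", post)
print("  emotions:", sorted(classify_emotions(post).labels))
print("  buckets: ", sorted(classify_buckets(post)))

# bucket -> theme attribution for one post
themes = assign_corpus_themes(anon)
p = anon.posts[0]
attr = map_subsentiments(classify_buckets(p), themes[p.post_id].theme_set)
print("  attribution for first corpus post:", {k: sorted(v) for k, v in attr.items()})

# user-level prevalence over the high-risk cohort
post_buckets = {q.post_id: classify_buckets(q) for q in anon.posts}
user_buckets = user_label_union(post_buckets, anon.posts_by_user())
hr_cohort = sorted(u for u, r in user_risk.items() if r in ("high", "very_high"))
table = aggregate_prevalence(user_buckets, hr_cohort, "hr_users")
print(f"\nsentiments of {table.denominator} high-risk users (n, %):")
for row in table.rows:
    print(f"  {row.label:22} {row.n:5}  ({row.pct}%)")
# Percentages are round-half-away-from-zero of 100*n/denominator.
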