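"""Generate a synthetic forum corpus with ground truth.

The generator emulates the population structure of MDS patient/caregiver
forums: role mix, a high-risk subcohort, ~1% superusers with heavy-tailed
post counts, and per-post injection of PII, misspellings, duplicates and
trial mentions at known rates.
"""

from collections import Counter

from mdslisten import SynthConfig, generate_corpus

corpus, gt = generate_corpus(SynthConfig(n_users=300, seed=42))

print(f"posts:   {corpus.n_posts}")
print(f"threads: {corpus.n_threads}")
print(f"users:   {corpus.n_users}")
print(f"roles:   {dict(Counter(gt.user_role.values()))}")
print(f"risk:    {dict(Counter(gt.user_risk.values()))}")
print(f"superusers: {len(gt.superusers)}")
print(f"posts with planted PII: {sum(1 for s in gt.pii_spans.values() if s)}")
print()
print("sample post:")
print(" ", corpus.posts[0].text[:200], "...")
# Every planted marker (role phrase, risk surrogate, theme seed, emotion cue,
# PII span) is recorded in the ground truth, so downstream stages can be
# scored exactly.
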