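"""Patient/caregiver role classification and high-risk tagging.

Posts are labeled by key phrases ("I have MDS" vs "my husband was diagnosed
with MDS"); users get the 80%-majority role with a chronological fallback.
High-risk status comes from treatment surrogates (hypomethylating agents,
transplant, blasts >= 20%, ...).
"""

from collections import Counter

from mdslisten import (SynthConfig, anonymize_corpus, classify_corpus_risk,
                       classify_corpus_roles, generate_corpus, tokenize_username)

corpus, gt = generate_corpus(SynthConfig(n_users=300, seed=7))
anon, _ = anonymize_corpus(corpus, salt="demo")  # INN-normalizes brand names

decisions, _ = classify_corpus_roles(anon)
user_risk, _ = classify_corpus_risk(anon)

print("role decisions:", dict(Counter(d.role for d in decisions.values())))
print("rules used:    ", dict(Counter(d.rule_used for d in decisions.values())))
print("risk labels:   ", dict(Counter(user_risk.values())))

# compare against planted labels through the username-token map
token_of = {u: tokenize_username(u, "demo") for u in gt.user_role}
ok = total = 0
for user, planted in gt.user_role.items():
    tok = token_of[user]
    if planted in ("patient", "caregiver") and tok in decisions:
        total += 1
        ok += decisions[tok].role == planted
print(f"role recovery: {ok}/{total} = {100 * ok / total:.1f}%")

ok = total = 0
for user, planted in gt.user_risk.items():
    tok = token_of[user]
    if planted == "high" and tok in user_risk:
        total += 1
        ok += user_risk[tok] == "high"
print(f"high-risk recovery: {ok}/{total} = {100 * ok / total:.1f}%")
# Both are 100% by construction: markers are lexical and planted verbatim.
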