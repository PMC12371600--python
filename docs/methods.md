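# Methods

`mdslisten` is a pipeline for mining patient and caregiver experience from
public forum posts about myelodysplastic syndromes (MDS), with a focus on
isolating and profiling the high-risk (HR-MDS) subcohort. Real forum scrapes
cannot be redistributed, so the package pairs every analysis stage with a
seedable synthetic-corpus generator whose ground truth is exact; everything
below describes both the procedure and what the synthetic validation does and
does not establish.

## Corpus model and cleaning

A corpus is a flat list of posts (id, thread, username, day-resolution
timestamp, source site, free text) with derived thread and user tables.
Cleaning applies, in order:

1. **Deduplication.** The duplicate key is *(username, whitespace/case-
   normalized text)*; the earliest copy is kept. Cross-posting by the same
   author is the dominant duplication mode on forums, so distinct users who
   quote identical text are not collapsed.
2. **Encoding validation.** Posts whose text is not valid UTF-8 (lone
   surrogates from undecodable bytes) are flagged and excluded.
3. **Spell autocorrection.** An out-of-dictionary token is replaced by its
   unique best in-dictionary neighbour within Damerau–Levenshtein distance 1
   (deletion, insertion, substitution, or adjacent transposition); ties break
   by dictionary frequency, then lexicographically. In-dictionary tokens are
   never altered and the token count never grows. The bundled dictionary is a
   small frequency-weighted word list covering general and hematology forum
   vocabulary; users can substitute a larger one.
4. **Exclusion filters.** Posts outside the configurable study window
   (default 2008-01-01..2022-12-31, both endpoints inclusive) and posts
   matching news/article or drug-approval cue phrases — content without
   personal patient or caregiver experience — are removed, with per-rule
   counts reported.

## De-identification

De-identification is lexicon- and rule-driven, not model-driven, so every
replacement is auditable:

- person names (bundled given-name/surname lists, consecutive name tokens
  merged) → `NAME`;
- professional title + capitalized name (`Dr Smith`) → `PROVIDER NAME`;
- drug manufacturers → `PRODUCT MANUFACTURER`;
- emails, phone numbers, and links → removed (no placeholder);
- an institution allowlist (NCI, Dana Farber, …) is matched first and kept
  verbatim;
- brand drug names → their International Nonproprietary Names via the bundled
  eight-row table (Venclexta → venetoclax, …), whole-word and
  case-insensitive. Misspelled brands are not fuzzy-matched; the spell
  corrector runs earlier in the pipeline.

Every action is recorded as *(span, category, replacement)* in a scrub audit;
replaying the audit against the original text reproduces the scrubbed text
exactly, and both scrubbing and brand mapping are idempotent.

Usernames are replaced by 12-hex-character keyed-hash (HMAC-SHA256) tokens.
The salt comes from configuration and is never logged or reported. Tokens are
deterministic per (user, salt) — posting histories stay linkable — and are
re-derived with a counter in the rare case a token shares a ≥3-character
substring with the original username. Token collisions between distinct users
are fatal rather than silently merged.

Posts naming an investigational agent (bundled list: sabatolimab, magrolimab,
pevonedistat, imetelstat, tamibarotene) or asserting first-person trial
participation ("I enrolled/started/joined … trial" within one sentence) are
dropped entirely; passing references to trials as an option are kept. The
keep/drop boundary follows the worked example of the source methodology
rather than its broader (self-contradicting) exclusion sentence.

## Role classification

Per post, key phrases decide the label with confidence 1.0: first-person
disease phrases ("I have MDS", "I was diagnosed with MDS", "I am living with
MDS", "I suffer from MDS") mark a patient; kin-noun patterns ("my husband was
diagnosed with MDS", "I care for my mother") mark a caregiver. "MDS" in any
phrase also matches the spelled-out disease name. If both phrase families
match, the earlier match position wins. Phrase-free posts may be delegated to
a pluggable classifier (`text -> (label, confidence)`); a reference
term-frequency + logistic-regression classifier trained on synthetic corpora
ships with the package.

Per user, a role held by ≥80% of the user's *labeled* posts wins (boundary
inclusive; unlabeled posts carry no role evidence and are excluded from the
denominator). Otherwise posts are scanned chronologically and the first label
with confidence ≥0.9 (configurable) is taken; if nothing qualifies the user
stays unknown.

## High-risk tagging

A post is HR-MDS evidence if it mentions any of: a hypomethylating agent
(azacitidine, decitabine), venetoclax, progression to AML,
allogeneic/haploidentical/stem-cell/bone-marrow transplantation, donor
lymphocyte infusion, erythropoietin failure, repeated transfusions (plural
form, or singular with a frequency cue within two tokens), intensive or
induction chemotherapy, an explicit "high-risk" self-description, or a blast
percentage ≥ 20. Blast values are numbers written as `N%`/`N percent` within
six tokens (configurable) of a blast mention; six tokens captures "blasts
were at 22%" without cross-sentence leakage. Texts are INN-normalized before
tagging so brand mentions hit the generic-name lists.

Per user: any marker ⇒ `high`. The reserved `low` / `intermediate` /
`very_high` labels fire only on explicit textual self-reports ("low risk
MDS"); an explicit lower-risk statement does **not** veto surrogate-derived
high — users progress — but the conflict is surfaced for logging. "Very high
risk" is excluded from the explicit high-risk pattern so the two strata stay
distinct.

## Themes

Two parallel label systems are kept, because their relationship is not
defined by the methodology being reproduced:

- **Five root themes** (disease burden, treatment decision, unmet needs,
  life milestones, logistic burden) with subtheme branches, each node mapping
  to ≥1 root and carrying an actionability flag (emotional-support content is
  the canonical nonactionable case).
- **Seven broad categories** (clinical, diet and lifestyle, education and
  logistics, emotional, physical, transplants, treatments).

The reference top-down classifier is seeded-keyword scoring — a label is
assigned when any of its seed phrases matches, with score = fraction of seeds
matched — chosen for auditability; a supervised classifier can be plugged in
behind the same interface. Bottom-up, latent topics come from LDA, LSA,
k-means, spectral, agglomerative, DBSCAN, or OPTICS over term-frequency or
tf-idf vectors (lowercased, English stopwords removed, minimum document
frequency 2), all deterministic for a fixed seed. A reviewer mapping folds
each latent topic into the hierarchy (attach to a node, create a subtheme
seeded with the topic's top terms, or discard); merges never remove nodes.

**Prevalence** of a theme is the number of unique discussions (threads)
containing ≥1 post assigned it. A theme is **major** when prevalence ≥ a
threshold, by default 5% of discussions (at least 1), boundary inclusive.
The **co-mention network** connects two themes with integer weight equal to
the number of discussions mentioning both; zero-weight pairs are absent,
self-loops impossible, and weight(a,b) ≤ min(prevalence(a), prevalence(b)).

## Sentiment

Emotions use a seven-way multilabel scheme (neutral, sadness, joy, surprise,
fear, disgust, anger) plus finer worry/hopefulness labels; the HR cohort is
additionally profiled with sub-sentiment buckets (concern, anxiety,
frustration, fear, confusion, information seeking), each attributed to a
disjoint set of theme-hierarchy topics (e.g. concern → blood counts, disease
burden, quality of life, treatment options, disease progression). The fear
bucket and the fear emotion intentionally share one cue list.

The default scorer is a transparent cue lexicon (score 1 iff a cue phrase
matches; classes at or above the cutoff, default 0.5, are set; neutral fires
iff nothing else does). It is co-designed with the synthetic generator so
that planted labels are recoverable exactly — which validates the
*aggregation machinery*, not lexical sentiment analysis of real prose. The
scorer interface accepts any model returning per-class scores; a fine-tuned
transformer could be substituted without touching aggregation.

User-level labels are the union of post-level labels (the weakest assumption
consistent with user-denominated reporting), each user counted at most once
per label. Percentages are `round-half-away-from-zero(100·n/denominator)`.

## Engagement, saturation, temporal splits

- **Engagement**: per-user activity span (last − first post date), with a
  min/median/max summary and the fraction of users disengaging within 2 days.
- **Superusers**: the top ~1% of users by post count (ties at the cut
  included). Their influence is normalized by capping their contribution to
  each discussion at `cap` posts (default 1, earliest kept) rather than
  winsorizing scores, matching the discussion-level prevalence unit; capping
  can only decrease aggregate counts.
- **Saturation**: posts are processed chronologically in batches (default
  500); significance = reaching major status on the full corpus. The
  saturation index is the smallest batch *b* with no significant theme first
  appearing in batches (b, b+lookahead] (lookahead default 3, window
  truncated at the corpus end but required non-empty). A windowed criterion
  operationalizes "no new themes emerge", which is unverifiable mid-stream.
- **Pandemic split**: matched pre-period 2018-01-01..2020-02-29, post-period
  from 2020-03-01; earlier posts go to an excluded bucket. The three buckets
  partition the corpus exactly.

## Synthetic generator

Post text is template-based slot filling, never free generation: every
planted marker (role phrase, risk surrogate, theme seed, emotion cue, PII
surface) appears verbatim at a recorded offset, so ground truth is exact and
the lexical downstream rules are testable. Defaults emulate the corpus
statistics the analysis was designed around: 2000 users with role mix
patient 0.49 / caregiver 0.42 / other 0.09; 31% high-risk users, each
guaranteed ≥1 surrogate-marker post (sometimes realized as a brand name to
exercise INN normalization); 1% superusers; per-user post counts a mixture of
Poisson(mean ≈ 7.5) regulars and Poisson(mean ≈ 300) superusers, giving a
heavy tail and ~10.5 posts/user overall; activity spans lognormal with
median ≈ 10 days and a tail beyond 1000 days; timestamps spanning 2008–2022;
three source forums weighted by their published post volumes; an emotion mix
of neutral .37 / sadness .22 / joy .20 / surprise .13 / fear .04 /
disgust .02 / anger .02; per-post sub-sentiment cue rates calibrated so
user-level union rates echo the reported HR sentiment prevalences. PII,
misspelling, duplicate, and trial-mention injection rates default to 0.05,
0.10, 0.02, and 0.01 per post — plausible forum rates chosen once, as no
source states them. Injected misspellings come from a fixed map whose entries
are distance-1 corruptions of dictionary words, so the cleaner can provably
restore them.

What passing on synthetic corpora shows: the de-identification, role, risk,
prevalence, network, saturation, and split machinery are correct against
exact ground truth, end to end and deterministically. What it does not show:
robustness to free-text paraphrase, misspelled markers, sarcasm, multilingual
content, or role/risk evidence expressed outside the lexicons — real-corpus
performance of the pluggable classifiers is out of scope.

## Numerical and degenerate-input choices

- All randomness flows through one `numpy` generator per run; identical
  config + seed gives byte-identical corpora and reports.
- Percentages: round half away from zero; no published value in scope is a
  .5 case, so the convention cannot conflict with printed numbers.
- Empty corpus: the pipeline completes with all-zero counts; empty cohorts
  produce empty tables (the low-level aggregation treats an empty cohort as a
  caller error).
- Spell-correction ties: frequency then lexicographic; boundary thresholds
  (80% majority, blast ≥20%, prevalence ≥ threshold) are all inclusive.
- Duplicate timestamps tie-break by input order (dedup) or post id
  (chronological scans).

## Known limitations

- Name scrubbing is list-based; names absent from the lists survive. The
  audit trail makes extending the lists cheap.
- The 80%-rule fallback classifier ships trained on synthetic text only and
  is a reference implementation of the interface, not a validated model.
- Only the `high` stratum is operationalized from surrogates;
  low/intermediate/very-high rely on explicit self-report.
- Theme seeds, emotion cues, and the category system are editable
  configuration, and results are only as good as those lexicons on real data.
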