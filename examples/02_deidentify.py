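"""De-identification: PII scrubbing, brand->INN mapping, username tokens.

Names become "NAME", provider mentions "PROVIDER NAME", manufacturers
"PRODUCT MANUFACTURER"; contact details are removed; allowlisted
institutions are kept; brand names become generic drug names; usernames
become stable keyed-hash tokens.
"""

from mdslisten import (BrandMap, PiiLexicon, filter_trial_posts, map_brand_to_inn,
                       scrub_pii, tokenize_username)
from mdslisten.resources import load_investigational_drugs

lexicon = PiiLexicon.default()
brands = BrandMap.default()

texts = [
    "Dr Smith said to wait, but Jane Brown suggested Dana Farber.",
    "Started Venclexta today, call 555-867-5309 with questions.",
    "The pharmacist said Pfizer makes this one.",
]
for text in texts:
    mapped = map_brand_to_inn(text, brands)
    scrubbed, audit = scrub_pii(mapped, lexicon)
    print(f"in : {text}")
    print(f"out: {scrubbed}   ({len(audit.actions)} replacements)")
    print()

# trial/investigational posts are excluded, passing references kept
inv = load_investigational_drugs()
for text in ("my oncologist recommended I look at clinical trials",
             "I decided to start a clinical trial of sabatolimab"):
    keep, reason = filter_trial_posts(text, inv)
    print(f"keep={keep!s:5} {reason or 'passing reference'}: {text!r}")

# same user + salt -> same token, so longitudinal post histories stay intact
print()
print("token for 'janedoe42':", tokenize_username("janedoe42", salt="demo-salt"))
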