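# Surrogate markers for tagging a post as evidence of high-risk MDS.
# Categories mirror the NCCN-aligned surrogates: hypomethylating agents,
# venetoclax, AML progression, transplantation, donor lymphocyte infusion,
# erythropoietin failure, repeated transfusions, intensive chemotherapy,
# explicit "high-risk" self-description, and blast percentages >= 20.
# Texts are expected to be INN-normalized first, so brand names (Vidaza,
# Venclexta, ...) arrive here as their generic names.
categories:
  explicit_high_risk: ["high-risk", "high risk", "higher-risk", "higher risk"]
  hypomethylating_agent: [azacitidine, decitabine, "hypomethylating agent"]
  venetoclax: [venetoclax]
  aml_progression: ["progressed to aml", "progression to aml", "transformed to aml",
                    "transformed into aml", "turned into aml", "developed aml"]
  transplant: ["allogeneic hematopoietic cell transplant", "haploidentical transplant",
               "stem cell transplant", "stem cell transplantation",
               "bone marrow transplant", "allogeneic transplant"]
  donor_lymphocyte_infusion: ["donor lymphocyte infusion", dli]
  erythropoietin_failure: ["erythropoietin failed", "epo failed", "failed erythropoietin",
                           "epo stopped working", "erythropoietin stopped working",
                           "not responding to erythropoietin", "epo did not help"]
  intensive_chemotherapy: ["intensive chemotherapy", "induction chemotherapy", "7+3"]
# multiple_transfusions is rule-based: a transfusion mention with a plural or
# frequency cue (see risk.py); the word lists below feed that rule.
transfusion_words: [transfusion, transfusions]
transfusion_frequency_cues: [another, weekly, monthly, regular, frequent, multiple, more, again]
blast_threshold: 20
blast_token_window: 6
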