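# Cue lexicon for the default (transparent) emotion scorer.
# Classes follow the seven-way scheme used throughout the package; neutral
# carries no cues and fires only when nothing else does.  The high-risk
# sub-sentiment buckets and the finer labels are scored from the same
# mechanism.  Cue sets are pairwise disjoint so that planted labels in
# synthetic corpora are recoverable exactly.
classes:
  sadness: [heartbroken, devastated, grieving, tearful, sorrowful, mourning]
  joy: [overjoyed, thrilled, delighted, celebrating, joyful, "wonderful news"]
  surprise: [shocked, stunned, astonished, unexpected, "caught me off guard"]
  fear: [terrified, frightened, scared, afraid, dreading]
  disgust: [disgusted, revolting, nauseating, repulsed]
  anger: [furious, outraged, angry, infuriating, livid]
finer:
  worry: [uneasy, apprehensive, "keeps me up at night", fretting]
  hopefulness: [hopeful, optimistic, encouraged, "looking forward"]
buckets:
  concern: [concerned, concerning, troubling, "weighs on me"]
  anxiety: [anxious, anxiety, "on edge", panicking]
  frustration: [frustrated, frustrating, "fed up", exasperated]
  fear: [terrified, frightened, scared, afraid, dreading]
  confusion: [confused, confusing, baffled, "makes no sense", "hard to understand"]
  information_seeking: ["does anyone know", "any advice", "has anyone tried",
                        "where can i find", "looking for information"]
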