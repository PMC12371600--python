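brand,inn
Venclexta,venetoclax
Tibsovo,ivosidenib
Xospata,gilteritinib
Velcade,bortezomib
Daurismo,glasdegib
Idhifa,enasidenib
Mylotarg,gemtuzumab ozogamicin
Clolar,clofarabine
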