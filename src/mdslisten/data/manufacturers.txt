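Pfizer
Novartis
Celgene
Bristol Myers Squibb
Bristol-Myers Squibb
AbbVie
Genentech
Astellas
Agios
Jazz Pharmaceuticals
Takeda
Otsuka
Sanofi
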