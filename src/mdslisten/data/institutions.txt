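NCI
National Cancer Institute
Dana Farber
Dana-Farber
Memorial Sloan Kettering
MD Anderson
Mayo Clinic
Cleveland Clinic
Johns Hopkins
Fred Hutchinson
OSUCCC
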