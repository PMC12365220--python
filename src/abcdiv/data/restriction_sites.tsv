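# Common restriction sites excluded from designed sequences by default
# (enzymes routinely used when assembling AAV expression constructs).
# name	site
NheI	GCTAGC
HindIII	AAGCTT
EcoRI	GAATTC
KpnI	GGTACC
BspEI	TCCGGA
NcoI	CCATGG
BsrGI	TGTACA
AscI	GGCGCGCC
SalI	GTCGAC
NotI	GCGGCCGC
SpeI	ACTAGT
BstBI	TTCGAA
EcoRV	GATATC
XhoI	CTCGAG
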