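srna	hfq_dependent
OxyS	true
DsrA	true
CyaR	true
ArcZ	true
RybB	true
MicA	true
GlmZ	true
RyeA	true
RyeB	true
CydC	true
SgrS	true
Ffs	false
RygD	false
CsrC	false
RdlD	false
RdlA	false
GadY	false
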