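canonical_name	aliases	hfq_dependent
OxyS		true
DsrA		true
CyaR		true
ArcZ		true
RybB		true
MicA		true
GlmZ		true
RyeA		true
RyeB		true
CydC		true
RyjB		true
SgrS		true
Ffs	4.5S	false
RygD		false
CsrC		false
RdlD		false
RdlA		false
GadY		false
PsrD		false
RygC		false
RyfD		false
RyfA		false
RybA		false
RyrC		false
RyeD		false
RydB		false
IsrB		false
IsrC		false
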