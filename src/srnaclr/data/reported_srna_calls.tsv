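comparison	direction	srna
dYbeY-Unt_vs_WT-Unt	up	CyaR
dYbeY-Unt_vs_WT-Unt	up	RyfA
dYbeY-Unt_vs_WT-Unt	up	Ffs
dYbeY-Unt_vs_WT-Unt	up	IsrC
dYbeY-Unt_vs_WT-Unt	down	RdlD
WT-HU_vs_WT-Unt	up	Ffs
WT-HU_vs_WT-Unt	up	RyhB
WT-HU_vs_WT-Unt	up	SgrS
WT-HU_vs_WT-Unt	up	GadY
WT-HU_vs_WT-Unt	up	CsrC
WT-HU_vs_WT-Unt	up	OxyS
WT-HU_vs_WT-Unt	up	RyfD
WT-HU_vs_WT-Unt	up	GlmZ
WT-HU_vs_WT-Unt	down	RyhA
WT-HU_vs_WT-Unt	down	RybB
WT-HU_vs_WT-Unt	down	RybA
WT-HU_vs_WT-Unt	down	RyfA
WT-HU_vs_WT-Unt	down	RygC
WT-HU_vs_WT-Unt	down	MicA
WT-HU_vs_WT-Unt	down	SymR
WT-HU_vs_WT-Unt	down	RyeA
WT-HU_vs_WT-Unt	down	RygD
dYbeY-HU_vs_dYbeY-Unt	up	IsrB
dYbeY-HU_vs_dYbeY-Unt	up	CyaR
dYbeY-HU_vs_dYbeY-Unt	up	RyeC
dYbeY-HU_vs_dYbeY-Unt	up	RyeD
dYbeY-HU_vs_dYbeY-Unt	up	RyjB
dYbeY-HU_vs_dYbeY-Unt	up	RdlD
dYbeY-HU_vs_dYbeY-Unt	up	RyhB
dYbeY-HU_vs_dYbeY-Unt	up	Ffs
dYbeY-HU_vs_dYbeY-Unt	up	OxyS
dYbeY-HU_vs_dYbeY-Unt	down	SymR
dYbeY-HU_vs_dYbeY-Unt	down	RydC
dYbeY-HU_vs_dYbeY-Unt	down	RdlA
dYbeY-HU_vs_dYbeY-Unt	down	RyeA
dYbeY-HU_vs_WT-HU	up	RygC
dYbeY-HU_vs_WT-HU	up	OxyS
dYbeY-HU_vs_WT-HU	up	CyaR
dYbeY-HU_vs_WT-HU	up	RyhA
dYbeY-HU_vs_WT-HU	up	RyfA
dYbeY-HU_vs_WT-HU	up	RygD
dYbeY-HU_vs_WT-HU	up	RybB
dYbeY-HU_vs_WT-HU	up	RybA
dYbeY-HU_vs_WT-HU	up	PsrD
dYbeY-HU_vs_WT-HU	up	IsrC
dYbeY-HU_vs_WT-HU	up	Ffs
dYbeY-HU_vs_WT-HU	up	RyjB
dYbeY-HU_vs_WT-HU	up	DsrA
dYbeY-HU_vs_WT-HU	up	RydB
dYbeY-HU_vs_WT-HU	up	ryeB
dYbeY-HU_vs_WT-HU	down	RdlA
dYbeY-HU_vs_WT-HU	down	SgrS
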