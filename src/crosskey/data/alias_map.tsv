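raw	normalized
DK1	CDK1
RACGAP	RACGAP1
BBCL2	BCL2
GF1	IGF1
CDK1A	CDKN1A
PPTG1	PTTG1
KIF20AK	KIF20A
CXL12	CXCL12
TK	TK1
MELKPBK	MELK;PBK
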