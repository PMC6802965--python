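name	consensus	family
K50_HD	TAATCC	K50
Q50_HD	TAATTR	Q50
Ebox	CANNTG	Ebox
CTCF	CCACCAGGGGGC	CTCF
NR_halfsite	RGGTCA	NR
MADS	CTAWWWWTAG	MADS
CRE	TGACGTCA	other
GC_box	GGGCGG	other
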