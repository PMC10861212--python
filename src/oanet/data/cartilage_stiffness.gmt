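CARTILAGE_STIFFNESS	genes whose knockout/knockdown decreases cartilage ECM stiffness	BMP2	CHAD	COL3A1	COL6A1	COL9A1	COL11A1	EGFR	MATN2	MATN3	MATN4	PRG4
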