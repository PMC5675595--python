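motif_id	rbp_name	iupac_pattern
SRSF1_1	SRSF1	KGRWGSM
DECOY_01	decoyA	UUUUAUU
DECOY_02	decoyB	RCGCGY
DECOY_03	decoyC	AUWUAUA
DECOY_04	decoyD	GCAUGM
DECOY_05	decoyE	YACAYAC
DECOY_06	decoyF	CUKCUUC
DECOY_07	decoyG	ACGUACG
DECOY_08	decoyH	WGGACWG
DECOY_09	decoyI	UCAYUCA
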