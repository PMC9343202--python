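pair_id	mirna_seq	cts_seq	label
pair_0001	UGAGGUAGUAGGUUGUAUAGUU	ACUAUACAACCUACUACCUCAACCUUAGGA	1
pair_0002	UAUUGCACUUGUCCCGGCCUGU	GGAUACGUUCAGGGCAAGUACGGAUCCAAU	1
pair_0003	AGCUUAUCAGACUGAUGUUGAC	GGCAUGCAUCCAUAGGACCAUAGGCAUCCA	0
pair_0004	CAUUGCACUUGUCUCGGUCUGA	UUGGCAACAUCAGUCUGAUAAGCUAGCCGG	0
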