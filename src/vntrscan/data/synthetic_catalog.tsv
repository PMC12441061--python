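# motif_id	sequence
SYN01	GTTTCAGCGGGCCGGCAGGCCCGCGCCGGGCGGCCAGGTCGACCGGGCGCCCCACGGCTC
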