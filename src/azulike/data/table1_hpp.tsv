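seq_id	hpp
azurin	49
p28-azurin	46
p2seq05	46
p3seq17	49
p3seq16	45
p3seq24	45
p2seq14	46
p2seq08	48
p2seq33	48
p2seq32	49
p2seq18	51
p2seq20	51
p1seq09	49
p1seq16	44
p3seq02	48
p3seq04	45
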