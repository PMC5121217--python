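sample_id	day	productivity
S01	0.0	0.5
S02	1.0	0.9
S03	2.0	1.5
S04	3.0	2.2
S05	4.0	3.0
S06	5.0	3.9
S07	6.0	3.0
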