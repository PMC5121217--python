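otu_id	S01	S02	S03	S04	S05	S06	S07
OTU_000	39	72	81	135	225	347	209
OTU_001	640	791	610	665	637	546	566
OTU_002	321	285	237	313	277	277	288
OTU_003	215	189	240	220	192	184	231
OTU_004	189	162	116	108	108	235	203
OTU_005	119	197	273	94	169	75	119
OTU_006	155	92	40	94	128	72	94
OTU_007	89	76	60	63	24	71	67
OTU_008	77	16	150	113	41	68	78
OTU_009	64	37	104	95	102	63	85
OTU_010	17	65	20	92	43	41	30
OTU_011	75	18	69	8	54	21	30
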