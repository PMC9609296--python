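# Example terminal scores over the morphotype-relevant characters,
# compiled from published state assignments for four reference taxa:
# one typical P5-swimmer, two taxa with a fully reversed (walking) P5,
# and one unusual long-merus swimmer lacking the propodus lobe.
taxon	7	8	11	15	16	18	23	34	35	42	43	44	45	46	47	48	50
Liocarcinus depurator	1	1	1	1	1	2	0	2	-	0	0	1	1	1	1	1	0
Carcinus maenas	1	1	1	1	1	2	0	1	2	0	0	0	0	0	0	0	0
Chaceon mediterraneus	1	1	1	1	1	2	0	0	-	0	0	0	0	0	0	0	0
Xaiva biguttata	1	1	1	1	1	2	0	3	2	0	0	0	1	0	1	1	0
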