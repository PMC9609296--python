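# P5-swimmer morphotype rule: character states required of every
# P5-swimming crab. Columns: char_id <TAB> allowed_states (comma-sep).
char_id	allowed_states
11	1
15	1
16	1
18	2
23	0
34	2,3
43	0
45	1
46	1
47	1
48	1
50	0
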