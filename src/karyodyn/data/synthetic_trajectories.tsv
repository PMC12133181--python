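population	generation	n_xxy_females	n_xx_females	n_males_total
pop1	1	77	78	132
pop1	2	71	66	150
pop1	3	55	82	150
pop1	4	46	85	156
pop1	5	45	78	164
pop1	6	33	89	165
pop1	7	28	116	143
pop1	8	19	116	152
pop1	9	20	140	127
pop1	10	13	136	138
pop1	11	11	139	137
pop1	12	4	127	156
pop2	1	81	66	140
pop2	2	77	65	145
pop2	3	59	90	138
pop2	4	61	83	143
pop2	5	47	91	149
pop2	6	38	115	134
pop2	7	48	93	146
pop2	8	19	116	152
pop2	9	19	111	157
pop2	10	19	128	140
pop2	11	11	119	157
pop2	12	8	131	148
pop3	1	76	80	131
pop3	2	73	71	143
pop3	3	47	102	138
pop3	4	50	107	130
pop3	5	37	116	134
pop3	6	31	106	150
pop3	7	21	112	154
pop3	8	17	122	148
pop3	9	16	146	125
pop3	10	13	124	150
pop3	11	13	135	139
pop3	12	5	145	137
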