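herb_id	display_name	LNE	LE	XO	L5	COX1	L12
a_dahurica	A. dahurica	94	149	74	98	25[lit:hwang2002]	-
a_pubescens	A. pubescens	88	85	73	85	5	83
a_sinensis	A. sinensis	95	94	90	0	0[lit:chao2010]	-
a_membranaceus	A. membranaceus	89	79	116	37	28	101
a_macrocephala	A. macrocephala	91	108	89	86	56	110
c_pilosula	C. pilosula	94	94	99	62	66	-
c_chinensis	C. chinensis	57	17	79	44	11	30
c_aromatica	C. aromatica	92	77	54	86	111	106
f_suspensa	F. suspensa	3	28	20	24	50[lit:kim2009]	119
l_edodes	L. edodes	92	85	88	104	67	91
p_lactiflora	P. lactiflora	74	63	56	72	30	96
p_amurense	P. amurense	60	20	85	0	14	35
p_cocos	P. cocos	94	112	75	39	25	44
r_glutinosa	R. glutinosa	92	73	79	104	61	120
s_baicalensis	S. baicalensis	2	1	-	0[lit:kim2009]	0[lit:ye2015]	-
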