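# taxon	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24	25	26	27	28	29	30	31	32	33	34	35	36	37	38	39	40	41	42	43	44	45	46	47	48
N. punctata	0	0	1	0	-	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	-	0	0	0	0	0	0	0	0	0	0	0	0	-	0	-	0	-	-	-	0	0	0	0	-	0
O. flexuosus	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	-	0	1	0	0	0	0	0	0	0	0	0	0	-	0	-	0	-	-	-	0	0	0	0	-	0
S. phuketensis	1	1	0	0	1	0	0	2	1	-	0	4	2	2	0	0	0	1	0	1	0	0	-	0	0	0	0	1	0	0	1	-	-	-	1	0	1	0	0	-	-	-	0	0	0	0	-	0
F. pacifica	1	0	0	0	2	0	1	2	0	1	1	1	1	0	0	0	0	1	0	1	0	0	-	1	-	1	0	0	0	0	0	1	0	0	0	-	0	-	1	0	0	0	0	2	0	0	-	0
H. maccullochae	1	1	1	0	-	0	1	2	1	-	0	1	2	1	0	2	1	1	0	2	1	1	0	1	-	1	0	0	0	1	0	1	1	0	0	-	0	-	1	0	1	0	1	-	-	0	-	1
H. arenaria	1	1	0	0	2	0	1	2	1	-	1	3	1	1	0	0	1	1	0	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	1	2	0	0	0	0	0	-	0
H. bengalensis	1	1	0	0	2	0	1	2	1	-	1	3	1	1	1	0	0	1	1	0	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	0	0	0	0	0	0	0	-	0
H. incisa	2	1	0	0	2	0	1	2	1	-	1	3	0	1	0	0	0	1	0	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	0	1	0	0	0	0	0	-	0
H. indooceanica	2	1	0	0	2	0	1	2	1	-	1	3	0	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	0	0	0	0	0	0	0	-	0
H. maxima	1	1	0	0	2	0	1	1	1	-	1	3	0	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	0	1	0	0	0	0	1	0	0
H. minima	0	1	0	0	2	0	1	1	1	-	1	3	1	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	1	2	0	0	1	0	0	-	0
H. peculiaris	0	1	0	0	2	0	1	1	1	-	1	3	0	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	1	0	0	1	0	0	0	-	0	-	1	1	2	0	1	-	-	0	-	0
H. riegerorum	2	1	0	1	2	0	1	1	1	-	1	3	2	0	1	0	0	1	0	1	0	0	-	0	0	1	0	0	1	0	0	1	2	0	0	-	0	-	1	1	2	0	0	0	1	1	1	0
H. unilamellata	0	1	0	0	2	0	1	1	1	-	1	3	0	1	1	0	0	1	0	2	0	0	-	0	0	1	1	0	1	0	0	1	0	0	0	-	0	-	1	0	0	0	0	2	0	0	-	0
M. aberrans	2	0	0	0	2	0	1	2	0	1	1	1	0	1	0	0	0	1	0	2	0	0	-	0	1	0	0	0	0	1	0	1	0	0	1	1	0	1	1	0	0	1	0	0	0	1	2	0
M. aggregatus	2	0	0	0	2	0	1	2	0	1	1	1	0	1	1	0	1	1	0	0	0	0	-	0	0	1	0	0	0	1	0	1	0	0	1	2	0	0	1	0	0	1	0	0	0	1	2	0
M. ancistrosylliformis	2	0	0	0	1	0	1	2	0	1	1	1	0	1	1	0	1	1	1	1	0	0	-	0	0	0	1	0	0	0	0	1	2	0	0	-	0	-	1	0	0	0	0	0	0	0	-	0
M. antarcticus	2	0	0	0	1	0	1	2	0	1	1	1	2	1	1	0	0	1	1	1	0	0	-	0	0	0	1	0	0	1	0	1	2	0	0	-	0	-	1	0	0	0	0	1	1	1	0	0
M. arenarius	1	1	0	0	2	0	1	2	0	1	1	1	0	1	1	0	0	1	1	2	0	0	-	0	0	1	1	0	0	1	0	1	0	0	1	0	0	1	1	0	0	0	0	0	0	1	2	0
M. coustalini	2	0	0	0	2	0	1	2	0	1	1	1	2	0	1	0	0	1	1	1	0	0	-	0	0	1	1	0	0	1	0	1	0	0	0	-	0	-	1	0	0	0	0	1	2	0	-	0
M. ephippiophorus	2	1	0	0	2	0	1	2	1	-	1	1	0	1	1	0	0	1	1	2	0	0	-	0	0	1	1	0	0	1	0	1	1	0	0	-	1	0	1	0	1	0	0	0	0	1	0	0
M. hamosus	2	0	1	0	-	0	1	2	0	1	1	1	0	1	1	1	0	1	1	1	1	1	0	0	0	1	0	0	0	1	0	1	2	0	0	-	0	-	1	2	1	0	1	-	-	0	-	1
M. hartmanae	2	0	0	0	1	0	1	2	0	1	1	1	1	1	1	0	0	1	1	1	0	0	-	0	1	1	1	0	0	0	0	1	0	1	1	1	1	1	1	0	0	1	0	1	0	0	-	0
M. hystrix	2	0	0	0	2	0	1	2	0	1	1	1	0	1	1	0	0	1	1	0	0	0	-	0	1	1	0	1	0	0	0	1	1	0	1	2	0	0	1	0	0	0	0	1	0	0	-	0
M. indefatigatus	2	0	0	0	2	0	1	2	0	1	1	1	0	2	1	0	0	1	1	0	0	0	-	0	1	1	1	1	0	1	0	1	2	0	1	1	0	1	1	0	0	1	0	1	0	0	-	0
M. itoi	1	1	0	0	2	0	1	2	1	-	1	1	1	0	1	0	0	1	1	1	0	0	-	0	1	1	1	0	0	1	0	1	2	0	1	2	0	0	1	0	0	1	0	0	1	0	-	0
M. listensis	0	0	0	0	2	0	1	2	0	1	1	1	0	2	1	0	0	1	1	2	0	0	-	0	0	1	1	0	0	1	0	1	1	0	0	-	0	-	1	0	0	0	0	1	0	1	2	0
M. mahensis	2	0	0	0	2	0	1	2	0	1	1	1	0	0	1	0	0	1	1	0	0	0	-	0	0	1	1	0	0	1	0	1	0	0	1	2	1	0	1	0	0	1	0	1	0	1	2	0
M. monilicornis	1	0	0	1	2	0	1	2	0	1	1	1	0	0	1	0	0	1	1	1	0	0	-	0	1	1	1	0	0	0	0	1	0	0	0	-	0	-	1	0	0	0	0	2	0	0	-	0
M. onychophorus	2	1	0	0	2	0	1	2	1	-	1	1	0	0	1	0	0	1	1	1	0	0	-	0	1	1	1	1	0	1	0	1	0	0	1	1	0	1	1	0	0	0	0	1	0	0	-	0
M. pseudaberrans	1	1	0	0	2	0	1	2	0	1	1	1	0	1	1	0	0	1	1	0	0	0	-	0	0	1	1	0	0	1	0	1	2	0	0	-	0	-	1	0	0	0	0	0	0	0	-	0
M. riseri	1	0	0	0	2	0	1	2	0	1	1	1	0	1	1	0	0	1	1	1	0	0	-	0	0	1	1	0	0	1	0	1	2	0	0	-	0	-	1	0	0	0	1	-	-	1	2	0
M. sczelkowii	1	0	0	0	2	1	1	2	0	1	1	1	0	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	0	1	0	1	2	0	0	-	0	-	1	0	0	0	0	0	0	1	2	0
M. simplicichaetosus	1	1	0	0	2	0	1	2	1	-	1	1	2	0	1	0	1	1	1	2	0	0	-	0	1	1	1	0	0	0	1	-	-	-	1	2	1	0	1	0	0	1	0	1	2	1	0	0
M. southerni	2	0	0	0	2	0	1	2	0	1	1	1	0	1	1	0	0	1	1	1	0	0	-	0	0	1	0	0	0	1	0	1	0	0	0	-	0	-	1	0	0	0	0	0	0	0	-	0
S. noodti	2	0	1	1	-	1	-	-	0	1	0	2	2	0	0	2	3	1	2	2	1	1	1	1	-	1	0	0	0	0	0	1	0	1	0	-	0	-	1	1	2	0	1	-	-	0	-	1
S. camposi	2	0	1	1	-	1	-	-	0	1	0	2	2	0	0	2	3	1	1	2	1	1	1	1	-	1	0	0	0	0	0	1	0	0	0	-	0	-	1	1	2	1	0	1	2	0	-	1
U. intermedia	2	0	1	0	-	0	1	2	0	1	1	1	1	1	0	2	1	1	2	1	1	1	0	0	0	1	0	0	0	1	0	1	0	0	0	-	0	-	1	0	0	0	0	0	2	0	-	0
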