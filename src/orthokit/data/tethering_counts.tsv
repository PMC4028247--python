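factor	yeast	arabidopsis	tomato
Uso1	1	1	1
COY1	1	1	1
Rud3/Grp1	1	0	0
Imh1	1	0	0
VPS11	1	1	1
VPS16	1	1	1
VPS18	1	1	1
VPS33	1	1	1
VPS39	1	1	2
VPS41	1	1	2
VPS8	1	1	1
VPS3	1	0	0
SEC3	1	2	1
SEC5	1	2	2
SEC6	1	1	1
SEC8	1	1	1
SEC10	1	1	4
SEC15	1	2	2
EXO70	1	14	12
EXO84	1	1	1
Tip20	1	1	0
DSL1	1	0	0
SEC39	1	0	0
COG1	1	1	1
COG2	1	1	1
COG3	1	1	1
COG4	1	1	1
COG5	1	1	1
COG6	1	1	1
COG7	1	1	1
COG8	1	1	1
VPS52	1	2	1
VPS53	1	2	1
VPS54	1	1	2
VPS51	1	0	0
Bet3	1	1	2
Bet5	1	1	1
Trs20	1	1	1
Trs23	1	1	1
Trs31	1	1	1
Trs33	1	1	1
Trs85	1	0	0
Trs120	1	1	1
Trs130	1	1	1
Trs65	1	0	0
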