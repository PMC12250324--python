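gene	entrez	promoters	direction	meth_diff_ind50
ASCL2	430	all	hyper	62.1
EPAS1	2034	all	hyper	62.1
FOXA3	3171	all	hyper	44.8
HOXA5	3202	all	hyper	55.1
HOXB3	3213	p1+p2+p4@HOXB3	hyper	37
HOXC4	3221	p3@HOXC4	hyper	39.8
IKZF4	64375	p1+p3@IKZF4	hyper	42
KDM2A	22992	p1@KDM2A	hyper	41.1
MSX2	4488	all	hyper	95.2
NR4A1	3164	p3@NR4A1	hyper	67.7
SALL4	57167	all	hyper	35.5
SOX13	9580	all	hyper	27.6
SP6	80320	p1+p2@SP6	hyper	34
TBX20	57057	all	hyper	25.1
TBX3	6926	all	hyper	56.5
TOE1	114034	all	hyper	29.2
ZKSCAN5	23660	all	hyper	93.9
ZNF93	81931	all	hyper	58.9
TBX1	6899	p1+p5@TBX1	hypo	-32.3
MYBL2	4605	all	hypo	-39.9
EGR3	1960	all	hypo	-38.9
ZNF331	55422	p4+p7@ZNF331	hypo	-98
THAP11	57215	all	hypo	-29
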