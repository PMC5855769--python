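species	group	clade	repeat_size_kb	n_over_1kb	n_over_100bp
B. rapa	spermatophyte	eudicot	3.80	1	9
B. napus	spermatophyte	eudicot	4.62	1	17
B. oleracea	spermatophyte	eudicot	152.00	2	24
A. thaliana	spermatophyte	eudicot	15.63	2	25
C. papaya	spermatophyte	eudicot	13.43	1	13
R. communis	spermatophyte	eudicot	5.80	6	6
G. max	spermatophyte	eudicot	60.67	13	68
V. radiata	spermatophyte	eudicot	1.02	0	6
S. latifolia	spermatophyte	eudicot	23.27	15	17
D. carota	spermatophyte	eudicot	71.09	4	19
N. tabacum	spermatophyte	eudicot	42.07	3	22
V. vinifera	spermatophyte	eudicot	5.77	0	26
S. polyrhiza	spermatophyte	monocot	1.58	0	5
P. dactylifera	spermatophyte	monocot	3.03	1	12
O. sativa japonica	spermatophyte	monocot	141.19	12	39
O. sativa indica	spermatophyte	monocot	141.76	11	27
S. bicolor	spermatophyte	monocot	58.56	5	18
Z. mays	spermatophyte	monocot	51.94	4	19
A. trichopoda	spermatophyte	basal_angiosperm	266.14	1	1811
C. taitungensis	spermatophyte	gymnosperm	62.65	2	5070
M. polymorpha	bryophyte	bryophyte	2.08	0	13
P. patens	bryophyte	bryophyte	0	0	0
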