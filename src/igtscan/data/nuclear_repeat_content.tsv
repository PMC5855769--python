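species	group	clade	repeat_mb	genome_mb	reported_pct
B. rapa	spermatophyte	eudicot	191.63	284.13	67.44
B. napus	spermatophyte	eudicot	441.77	930.51	47.48
B. oleracea	spermatophyte	eudicot	185.43	539.91	34.34
A. thaliana	spermatophyte	eudicot	23.58	119.67	19.70
C. papaya	spermatophyte	eudicot	316.53	369.78	85.60
R. communis	spermatophyte	eudicot	176.00	350.62	50.20
C. lanatus	spermatophyte	eudicot	159.80	321.05	49.77
G. max	spermatophyte	eudicot	587.10	978.97	59.97
V. radiata	spermatophyte	eudicot	216.17	548.08	39.44
S. latifolia	spermatophyte	eudicot	244.82	665.28	36.80
D. carota	spermatophyte	eudicot	193.70	473.00	40.95
N. tabacum	spermatophyte	eudicot	3479.49	4500.00	77.32
V. vinifera	spermatophyte	eudicot	185.35	487.00	38.06
S. polyrhiza	spermatophyte	monocot	19.43	132.01	14.72
P. dactylifera	spermatophyte	monocot	214.34	558.02	38.41
O. sativa japonica	spermatophyte	monocot	188.00	374.42	50.21
O. sativa indica	spermatophyte	monocot	148.14	374.25	39.58
S. bicolor	spermatophyte	monocot	231.28	739.15	31.29
Z. mays	spermatophyte	monocot	1757.48	2067.62	85.00
A. trichopoda	spermatophyte	basal_angiosperm	407.43	706.50	57.67
M. polymorpha	bryophyte	bryophyte	12.48	304.37	4.10
P. patens	bryophyte	bryophyte	79.37	477.95	16.61
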