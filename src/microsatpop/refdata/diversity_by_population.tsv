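population	group	A	Ae	Ho	He
L1	lignotuberous	8.4	5.2	0.63	0.76
L2	lignotuberous	8.5	4.0	0.59	0.72
L3	lignotuberous	8.5	4.9	0.59	0.77
L4	lignotuberous	8.9	5.0	0.65	0.77
L5	lignotuberous	8.4	4.2	0.64	0.73
L6	lignotuberous	8.0	4.7	0.62	0.76
E1	epicormic	7.2	4.0	0.58	0.69
E2	epicormic	7.6	4.2	0.62	0.70
E3	epicormic	8.1	5.0	0.57	0.74
E4	epicormic	8.2	4.6	0.53	0.70
E5	epicormic	8.2	4.7	0.62	0.73
E6	epicormic	8.4	5.4	0.55	0.76
E7	epicormic	8.0	5.0	0.54	0.71
E8	epicormic	8.3	4.7	0.58	0.71
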