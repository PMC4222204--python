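	L1	L2	L3	L4	L5	L6	E1	E2	E3	E4	E5	E6	E7
L2	-0.13
L3	-0.09	-0.03
L4	-0.11	-0.01	-0.05
L5	-0.08	-0.04	0.02	-0.05
L6	-0.14	-0.05	-0.06	-0.09	-0.06
E1	0.23	0.31	0.29	0.28	0.33	0.29
E2	0.19	0.28	0.27	0.25	0.29	0.26	0.01
E3	0.16	0.27	0.26	0.28	0.30	0.24	0.01	0.04
E4	0.20	0.31	0.33	0.27	0.28	0.23	0.10	0.08	0.11
E5	0.22	0.29	0.30	0.29	0.29	0.27	-0.01	0.00	-0.01	0.07
E6	0.15	0.28	0.26	0.24	0.30	0.24	0.02	0.03	-0.05	0.13	-0.01
E7	0.13	0.25	0.28	0.32	0.36	0.30	-0.02	0.03	0.01	0.12	-0.02	0.04
E8	0.15	0.29	0.30	0.33	0.38	0.30	0.01	0.06	0.05	0.11	0.00	0.03	-0.05
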