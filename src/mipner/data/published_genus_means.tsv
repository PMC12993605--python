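genus	MIPNER	BINDER	MIXNER_A	MIXNER_B	SOIL_CULTURE	SOIL_SOURCE
Pseudomonas	43.1	4.86	8.66	7.81	7.06	0.78
Sphingobium	27.2	0	1.08E-03	0.01	0.01	0.26
Caulobacter	15.76	0	4.24E-03	0.01	0.01	0.12
Massilia	3.96	0.16	5.99	3.76	0.32	0.28
Cupriavidus	3.17	0.91	0.29	1.13	1.99	3.65
Enterobacter	2.44	81.27	0.88	0.94	72.56	2.75
Duganella	0.96	0.10	1.13	3.32	0.49	0.06
Burkholderia	0.49	2.27E-03	0.03	0.08	0.04	0.57
Bradyrhizobium	0.38	3.76E-04	0.01	0.01	6.26E-04	8.17
Janthinobacterium	0.35	0.17	15.11	9.60	1.09	0.04
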