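metabolite	hmdb_id	multiplicity	shift_lo	shift_hi	n_protons	provenance	decoy
Glucose-6-phosphate	HMDB0001401	multiplet	3.26	3.28	1	packaged	0
Glucose-6-phosphate	HMDB0001401	multiplet	3.47	3.51	1	packaged	0
Glucose-6-phosphate	HMDB0001401	multiplet	3.55	3.59	1	packaged	0
Glucose-6-phosphate	HMDB0001401	triplet	3.70	3.73	1	packaged	0
Glucose-6-phosphate	HMDB0001401	doublet	3.87	3.88	1	packaged	0
Glucose-6-phosphate	HMDB0001401	multiplet	3.90	3.94	1	packaged	0
Glucose-6-phosphate	HMDB0001401	triplet	3.98	4.00	1	packaged	0
Glucose-6-phosphate	HMDB0001401	multiplet	4.02	4.05	1	packaged	0
Glucose-6-phosphate	HMDB0001401	doublet	4.63	4.64	1	packaged	0
Glucose-6-phosphate	HMDB0001401	singlet	5.22	5.22	1	packaged	0
Glucuronic acid	HMDB0000127	multiplet	3.27	3.30	1	packaged	0
Glucuronic acid	HMDB0000127	multiplet	3.49	3.54	1	packaged	0
Glucuronic acid	HMDB0000127	quartet	3.57	3.59	1	packaged	0
Glucuronic acid	HMDB0000127	multiplet	3.72	3.75	1	packaged	0
Glucuronic acid	HMDB0000127	doublet	4.08	4.09	1	packaged	0
Glucuronic acid	HMDB0000127	singlet	4.64	4.64	1	packaged	0
Glucuronic acid	HMDB0000127	singlet	4.66	4.66	1	packaged	0
Glucuronic acid	HMDB0000127	doublet	5.24	5.25	1	packaged	0
Glyceric acid	HMDB0000139	multiplet	3.72	3.84	2	packaged	0
Glyceric acid	HMDB0000139	multiplet	4.12	4.14	1	packaged	0
Glycogen	HMDB0000757	singlet	3.83	3.83	5	packaged	0
Glycogen	HMDB0000757	singlet	5.39	5.39	1	packaged	0
Lactate	HMDB0000190	doublet	1.31	1.32	3	packaged	0
Lactate	HMDB0000190	quartet	4.08	4.12	1	packaged	0
Malic acid	HMDB0000156	quartet	2.33	2.38	1	packaged	0
Malic acid	HMDB0000156	doublet	2.64	2.65	1	packaged	0
Malic acid	HMDB0000156	doublet	2.67	2.68	1	packaged	0
Malic acid	HMDB0000156	quartet	4.28	4.31	1	packaged	0
Maltose	HMDB0000163	singlet	5.40	5.40	1	packaged	0
Maltose	HMDB0000163	doublet	5.22	5.23	1	packaged	0
Maltose	HMDB0000163	doublet	3.96	3.98	1	packaged	0
Maltose	HMDB0000163	doublet	3.93	3.94	1	packaged	0
Maltose	HMDB0000163	doublet	3.89	3.92	1	packaged	0
Maltose	HMDB0000163	multiplet	3.81	3.87	2	packaged	0
Maltose	HMDB0000163	multiplet	3.74	3.79	2	packaged	0
Maltose	HMDB0000163	multiplet	3.69	3.73	2	packaged	0
Maltose	HMDB0000163	quartet	3.65	3.68	1	packaged	0
Maltose	HMDB0000163	singlet	3.63	3.63	1	packaged	0
Maltose	HMDB0000163	multiplet	3.55	3.60	2	packaged	0
Maltose	HMDB0000163	triplet	3.39	3.43	1	packaged	0
Maltose	HMDB0000163	quartet	3.25	3.28	1	packaged	0
Arginine	HMDB0000517	multiplet	1.605	1.756	2	packaged	0
Arginine	HMDB0000517	multiplet	1.874	1.935	2	packaged	0
Arginine	HMDB0000517	triplet	3.220	3.248	2	packaged	0
Arginine	HMDB0000517	triplet	3.744	3.769	1	packaged	0
N-acetylglycine	HMDB0000532	singlet	8.00	8.00	1	packaged	0
N-acetylglycine	HMDB0000532	doublet	3.745	3.768	2	packaged	0
Proline	HMDB0000162	multiplet	1.94	2.09	3	packaged	0
Proline	HMDB0000162	multiplet	2.31	2.37	1	packaged	0
Proline	HMDB0000162	multiplet	3.30	3.35	1	packaged	0
Proline	HMDB0000162	multiplet	3.38	3.42	1	packaged	0
Proline	HMDB0000162	multiplet	4.11	4.13	1	packaged	0
Taurine	HMDB0000251	triplet	3.24	3.26	2	packaged	0
Taurine	HMDB0000251	triplet	3.40	3.43	2	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	quartet	4.32	4.35	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	doublet	3.48	3.49	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	singlet	3.46	3.46	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	singlet	3.37	3.37	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	doublet	3.34	3.35	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	multiplet	2.39	2.45	1	packaged	0
trans-4-hydroxy-L-proline	HMDB0000725	multiplet	2.12	2.17	1	packaged	0
Allantoin	HMDB0000462	singlet	5.38	5.38	1	packaged	0
Glycerophosphocholine	HMDB0000086	singlet	3.20	3.20	9	packaged	0
Glycerophosphocholine	HMDB0000086	multiplet	3.59	3.68	2	packaged	0
Glycerophosphocholine	HMDB0000086	multiplet	3.84	3.95	3	packaged	0
Glycerophosphocholine	HMDB0000086	quartet	4.29	4.33	2	packaged	0
Glucose	HMDB0000122	quartet	3.22	3.25	1	packaged	0
Glucose	HMDB0000122	singlet	3.38	3.38	1	packaged	0
Glucose	HMDB0000122	doublet	3.39	3.39	1	packaged	0
Glucose	HMDB0000122	doublet	3.40	3.41	1	packaged	0
Glucose	HMDB0000122	singlet	3.42	3.42	1	packaged	0
Glucose	HMDB0000122	doublet	3.43	3.44	1	packaged	0
Glucose	HMDB0000122	quartet	3.45	3.46	1	packaged	0
Glucose	HMDB0000122	quartet	3.46	3.46	1	packaged	0
Glucose	HMDB0000122	singlet	3.48	3.48	1	packaged	0
Glucose	HMDB0000122	singlet	3.49	3.49	1	packaged	0
Glucose	HMDB0000122	doublet	3.51	3.52	1	packaged	0
Glucose	HMDB0000122	doublet	3.53	3.54	1	packaged	0
Glucose	HMDB0000122	quartet	3.69	3.71	1	packaged	0
Glucose	HMDB0000122	multiplet	3.72	3.77	1	packaged	0
Glucose	HMDB0000122	doublet	3.80	3.81	1	packaged	0
Glucose	HMDB0000122	singlet	3.82	3.82	1	packaged	0
Glucose	HMDB0000122	doublet	3.82	3.83	1	packaged	0
Glucose	HMDB0000122	doublet	3.84	3.85	1	packaged	0
Glucose	HMDB0000122	doublet	3.87	3.88	1	packaged	0
Glucose	HMDB0000122	doublet	3.89	3.90	1	packaged	0
Glucose	HMDB0000122	doublet	4.63	4.64	1	packaged	0
Glucose	HMDB0000122	doublet	5.22	5.22	1	packaged	0
Glutamic acid	HMDB0000148	quartet	3.73	3.76	1	packaged	0
Glutamic acid	HMDB0000148	multiplet	2.00	2.15	2	packaged	0
Glutamic acid	HMDB0000148	singlet	2.29	2.29	1	packaged	0
Glutamic acid	HMDB0000148	singlet	2.31	2.31	1	packaged	0
Glutamic acid	HMDB0000148	doublet	2.32	2.33	1	packaged	0
Glutamic acid	HMDB0000148	doublet	2.34	2.34	1	packaged	0
Glutamic acid	HMDB0000148	doublet	2.35	2.36	1	packaged	0
Glutamic acid	HMDB0000148	singlet	2.38	2.38	1	packaged	0
Glutamic acid	HMDB0000148	singlet	2.39	2.39	1	packaged	0
Creatine	HMDB0000064	singlet	3.02	3.02	3	packaged	0
Creatine	HMDB0000064	singlet	3.92	3.92	2	packaged	0
Ethanolamine	HMDB0000149	triplet	3.12	3.14	2	packaged	0
Ethanolamine	HMDB0000149	triplet	3.80	3.82	2	packaged	0
Alanine	HMDB0000161	doublet	1.46	1.49	3	packaged	0
Alanine	HMDB0000161	quartet	3.76	3.79	1	packaged	0
Threonine	HMDB0000167	doublet	1.32	1.34	3	packaged	0
Threonine	HMDB0000167	doublet	3.57	3.59	1	packaged	0
Threonine	HMDB0000167	multiplet	4.24	4.27	1	packaged	0
Guanidinoacetic acid	HMDB0000128	singlet	3.79	3.80	2	packaged	0
Valine	HMDB0000883	doublet	0.97	0.99	3	packaged	1
Valine	HMDB0000883	doublet	1.02	1.05	3	packaged	1
Uracil	HMDB0000300	doublet	5.79	5.81	1	packaged	1
Uracil	HMDB0000300	doublet	7.52	7.54	1	packaged	1
Inosine	HMDB0000195	doublet	6.08	6.10	1	packaged	1
Inosine	HMDB0000195	singlet	8.22	8.24	1	packaged	1
Inosine	HMDB0000195	singlet	8.33	8.35	1	packaged	1
Tyrosine	HMDB0000158	doublet	6.88	6.91	2	packaged	1
Tyrosine	HMDB0000158	doublet	7.17	7.20	2	packaged	1
Histidine	HMDB0000177	singlet	7.05	7.09	1	packaged	1
Histidine	HMDB0000177	singlet	7.75	7.79	1	packaged	1
Phenylalanine	HMDB0000159	multiplet	7.30	7.34	2	packaged	1
Phenylalanine	HMDB0000159	multiplet	7.36	7.45	3	packaged	1
Formate	HMDB0000142	singlet	8.44	8.46	1	packaged	1
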