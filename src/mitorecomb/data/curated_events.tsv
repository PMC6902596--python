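species	length_bp	identity_pct	direction	copy1_pos	copy2_pos	master_count	master_pct	alt_count	alt_pct	gene_order_state	genes_affected
Bazzania japonica	51	94.12	direct	142103-142153	141693-141743	30	68.18	14	31.82	unchanged	trnSUGA
Bazzania japonica	66	87.88	direct	70639-70704	70053-70118	39	84.78	7	15.22	unchanged	atp8
Conocephalum conicum	138	93.48	direct	85167-85304	84355-84492	148	99.33	1	0.67	unchanged	cox2;cox3
Fossombronia cristula	73	98.63	inverted	60943-61014	58015-58087	67	57.76	49	42.24	unchanged
Fossombronia cristula	95	86.32	direct	45965-46059	46130-46221	67	60.91	43	39.09	unchanged
Fossombronia cristula	93	87.1	inverted	61247-61339	58038-58130	86	81.9	19	18.1	unchanged
Fossombronia cristula	52	96.15	direct	55570-55619	55443-55494	80	97.57	2	2.43	unchanged
Fossombronia cristula	73	98.63	direct	61341-61413	60943-61014	80	98.73	1	1.23	unchanged
Frullania orientalis	75	96	inverted	12671-12745	12671-12745	12	92.31	1	7.69	changed
Haplomitrium mnioides	77	88.31	direct	87784-87860	40562-40637	48	97.96	1	2.04	changed	cox3;trnSGCU
Haplomitrium mnioides	241	100	direct	140823-141063	132233-132473	95	98.96	1	1.04	changed
Haplomitrium mnioides	51	90.2	direct	14195-14245	14085-14135	35	97.2	1	2.8	unchanged
Heteroscyphus zollingeri	253	96.05	direct	66972-67223	21339-21591	27	96.43	1	3.57	changed	rps7
Monosolenium tenerum	138	92.03	direct	86651-86787	85840-85977	94	98.95	1	1.05	unchanged	cox2;cox3
Nowellia curvifolia	120	100	inverted	88658-88777	5529-5648	31	60.78	20	39.22	changed	cob
Nowellia curvifolia	138	98.55	inverted	88962-89099	5392-5529	62	78.48	17	21.52	changed	cob
Nowellia curvifolia	64	93.75	inverted	140191-140253	140191-140253	30	96.77	1	3.23	changed
Odontoschisma grosseverrucosum	52	94.23	inverted	94954-95005	5637-5688	32	40	48	60	changed	cob
Pleurozia purpurea	140	98.57	direct	113528-113667	108644-108788	21	95.46	1	4.54	unchanged	atp1
Plicanthus hirtellus	54	98.15	inverted	112052-112105	84436-84489	31	48.44	33	51.56	changed
Porella plumosa	62	90.32	inverted	45426-45485	45426-45485	20	95.24	1	4.76	changed
Radula japonica	114	89.47	direct	68120-68227	67321-67434	49	98	1	2	unchanged	cox2;cox3
Radula japonica	189	99.47	direct	142227-142415	79402-79590	67	98.53	1	1.47	changed
Riccia cavernosa	77	87.01	inverted	110110-110185	110110-110185	66	95.65	3	4.35	changed
Treubia lacunosa	137	93.43	direct	72748-72884	72001-72137	82	98.8	1	1.2	unchanged	cox2;cox3
Trichocolea tomentella	63	92.06	direct	151893-151955	151475-151537	14	82.35	3	17.65	unchanged	trnSUGA
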