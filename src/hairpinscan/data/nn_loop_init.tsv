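# Loop initiation free energies dG_i(n), kcal/mol, n = 1..30.
kind	n	dg
internal	1	1.7
internal	2	1.7
internal	3	1.8
internal	4	1.8
internal	5	2.0
internal	6	2.0
internal	7	2.2
internal	8	2.3
internal	9	2.4
internal	10	2.5
internal	11	2.6
internal	12	2.7
internal	13	2.8
internal	14	2.9
internal	15	2.9
internal	16	3.0
internal	17	3.1
internal	18	3.1
internal	19	3.2
internal	20	3.3
internal	21	3.3
internal	22	3.4
internal	23	3.4
internal	24	3.5
internal	25	3.6
internal	26	3.6
internal	27	3.7
internal	28	3.7
internal	29	3.7
internal	30	3.8
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
bulge	7	4.6
bulge	8	4.7
bulge	9	4.8
bulge	10	4.9
bulge	11	5.0
bulge	12	5.1
bulge	13	5.2
bulge	14	5.3
bulge	15	5.4
bulge	16	5.4
bulge	17	5.5
bulge	18	5.5
bulge	19	5.6
bulge	20	5.7
bulge	21	5.7
bulge	22	5.8
bulge	23	5.8
bulge	24	5.8
bulge	25	5.9
bulge	26	5.9
bulge	27	6.0
bulge	28	6.0
bulge	29	6.0
bulge	30	6.1
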