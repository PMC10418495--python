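energy	region	group	n	at	all_closed
0.250	I	OS	0	0	0
0.250	I	group1	0	0	0
0.250	I	group2	0	0	0
0.250	I	group3	0	0	0
0.250	I	group4	1	0	0
0.250	II	OS	5	1	0
0.250	II	group1	62	26	0
0.250	II	group2	3	2	0
0.250	II	group3	3	0	0
0.250	II	group4	13	6	0
0.250	III	OS	3	1	0
0.250	III	group1	9	5	0
0.250	III	group2	0	0	0
0.250	III	group3	0	0	0
0.250	III	group4	2	2	0
0.300	I	OS	0	0	0
0.300	I	group1	0	0	0
0.300	I	group2	0	0	0
0.300	I	group3	0	0	0
0.300	I	group4	0	0	0
0.300	II	OS	11	1	0
0.300	II	group1	8	1	0
0.300	II	group2	2	0	0
0.300	II	group3	1	1	0
0.300	II	group4	0	0	0
0.300	III	OS	2	2	0
0.300	III	group1	0	0	0
0.300	III	group2	0	0	0
0.300	III	group3	0	0	0
0.300	III	group4	34	31	0
0.350	I	OS	0	0	0
0.350	I	group1	0	0	0
0.350	I	group2	0	0	0
0.350	I	group3	0	0	0
0.350	I	group4	0	0	1
0.350	II	OS	0	0	0
0.350	II	group1	1	0	0
0.350	II	group2	4	2	0
0.350	II	group3	9	3	0
0.350	II	group4	0	0	1
0.350	III	OS	2	1	0
0.350	III	group1	0	0	0
0.350	III	group2	34	29	0
0.350	III	group3	0	0	0
0.350	III	group4	0	0	1
0.400	I	OS	0	0	0
0.400	I	group1	0	0	0
0.400	I	group2	0	0	0
0.400	I	group3	0	0	0
0.400	I	group4	0	0	1
0.400	II	OS	1	0	0
0.400	II	group1	1	0	0
0.400	II	group2	1	0	0
0.400	II	group3	1	0	0
0.400	II	group4	0	0	1
0.400	III	OS	0	0	0
0.400	III	group1	0	0	0
0.400	III	group2	0	0	0
0.400	III	group3	0	0	0
0.400	III	group4	0	0	1
0.450	I	OS	0	0	0
0.450	I	group1	0	0	0
0.450	I	group2	0	0	0
0.450	I	group3	0	0	1
0.450	I	group4	0	0	1
0.450	II	OS	38	13	0
0.450	II	group1	5	0	0
0.450	II	group2	0	0	0
0.450	II	group3	0	0	1
0.450	II	group4	0	0	1
0.450	III	OS	1	0	0
0.450	III	group1	0	0	0
0.450	III	group2	3	0	0
0.450	III	group3	0	0	1
0.450	III	group4	0	0	1
0.500	I	OS	0	0	0
0.500	I	group1	0	0	0
0.500	I	group2	0	0	1
0.500	I	group3	0	0	1
0.500	I	group4	0	0	1
0.500	II	OS	20	5	0
0.500	II	group1	20	5	0
0.500	II	group2	0	0	1
0.500	II	group3	0	0	1
0.500	II	group4	0	0	1
0.500	III	OS	0	0	0
0.500	III	group1	0	0	0
0.500	III	group2	0	0	1
0.500	III	group3	0	0	1
0.500	III	group4	0	0	1
0.550	I	OS	27	12	0
0.550	I	group1	0	0	1
0.550	I	group2	0	0	1
0.550	I	group3	0	0	1
0.550	I	group4	0	0	1
0.550	II	OS	259	121	0
0.550	II	group1	0	0	1
0.550	II	group2	0	0	1
0.550	II	group3	0	0	1
0.550	II	group4	0	0	1
0.550	III	OS	10	4	0
0.550	III	group1	0	0	1
0.550	III	group2	0	0	1
0.550	III	group3	0	0	1
0.550	III	group4	0	0	1
0.600	I	OS	0	0	1
0.600	I	group1	0	0	1
0.600	I	group2	0	0	1
0.600	I	group3	0	0	1
0.600	I	group4	0	0	1
0.600	II	OS	0	0	1
0.600	II	group1	0	0	1
0.600	II	group2	0	0	1
0.600	II	group3	0	0	1
0.600	II	group4	0	0	1
0.600	III	OS	0	0	1
0.600	III	group1	0	0	1
0.600	III	group2	0	0	1
0.600	III	group3	0	0	1
0.600	III	group4	0	0	1
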