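energy	region	group	n	at	all_closed
0.250	I	OS	0	0	0
0.250	I	group1	0	0	0
0.250	I	group2	1	1	0
0.250	I	group3	4	1	0
0.250	I	group4	31	20	0
0.250	II	OS	30	17	0
0.250	II	group1	21	9	0
0.250	II	group2	39	22	0
0.250	II	group3	9	2	0
0.250	II	group4	300	179	0
0.250	III	OS	54	39	0
0.250	III	group1	60	41	0
0.250	III	group2	41	31	0
0.250	III	group3	2	2	0
0.250	III	group4	183	130	0
0.300	I	OS	0	0	0
0.300	I	group1	0	0	0
0.300	I	group2	0	0	0
0.300	I	group3	0	0	0
0.300	I	group4	2	1	0
0.300	II	OS	8	5	0
0.300	II	group1	9	5	0
0.300	II	group2	2	0	0
0.300	II	group3	5	1	0
0.300	II	group4	18	9	0
0.300	III	OS	0	0	0
0.300	III	group1	0	0	0
0.300	III	group2	0	0	0
0.300	III	group3	0	0	0
0.300	III	group4	8	5	0
0.350	I	OS	0	0	0
0.350	I	group1	0	0	0
0.350	I	group2	0	0	0
0.350	I	group3	0	0	0
0.350	I	group4	0	0	1
0.350	II	OS	24	8	0
0.350	II	group1	10	9	0
0.350	II	group2	79	54	0
0.350	II	group3	2	0	0
0.350	II	group4	0	0	1
0.350	III	OS	0	0	0
0.350	III	group1	5	2	0
0.350	III	group2	120	97	0
0.350	III	group3	0	0	0
0.350	III	group4	0	0	1
0.400	I	OS	1	0	0
0.400	I	group1	0	0	0
0.400	I	group2	0	0	0
0.400	I	group3	0	0	0
0.400	I	group4	0	0	1
0.400	II	OS	33	8	0
0.400	II	group1	3	1	0
0.400	II	group2	33	10	0
0.400	II	group3	62	10	0
0.400	II	group4	0	0	1
0.400	III	OS	0	0	0
0.400	III	group1	0	0	0
0.400	III	group2	33	9	0
0.400	III	group3	10	3	0
0.400	III	group4	0	0	1
0.450	I	OS	2	0	0
0.450	I	group1	0	0	0
0.450	I	group2	0	0	0
0.450	I	group3	0	0	1
0.450	I	group4	0	0	1
0.450	II	OS	34	5	0
0.450	II	group1	0	0	0
0.450	II	group2	7	3	0
0.450	II	group3	0	0	1
0.450	II	group4	0	0	1
0.450	III	OS	2	0	0
0.450	III	group1	3	0	0
0.450	III	group2	0	0	0
0.450	III	group3	0	0	1
0.450	III	group4	0	0	1
0.500	I	OS	0	0	0
0.500	I	group1	0	0	0
0.500	I	group2	0	0	1
0.500	I	group3	0	0	1
0.500	I	group4	0	0	1
0.500	II	OS	100	25	0
0.500	II	group1	62	15	0
0.500	II	group2	0	0	1
0.500	II	group3	0	0	1
0.500	II	group4	0	0	1
0.500	III	OS	109	69	0
0.500	III	group1	67	43	0
0.500	III	group2	0	0	1
0.500	III	group3	0	0	1
0.500	III	group4	0	0	1
0.550	I	OS	0	0	0
0.550	I	group1	0	0	1
0.550	I	group2	0	0	1
0.550	I	group3	0	0	1
0.550	I	group4	0	0	1
0.550	II	OS	3	0	0
0.550	II	group1	0	0	1
0.550	II	group2	0	0	1
0.550	II	group3	0	0	1
0.550	II	group4	0	0	1
0.550	III	OS	0	0	0
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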