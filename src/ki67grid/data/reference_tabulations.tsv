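stratum	variable	level	rs_0_15	rs_16_19	rs_20_25	rs_gt25
age_lt50	hotspot	<10	1	1	3	0
age_lt50	hotspot	<20	23	14	0	0
age_lt50	hotspot	<30	20	8	4	2
age_lt50	hotspot	<40	20	9	7	4
age_lt50	hotspot	>=40	12	9	6	10
age_lt50	average	<10	37	19	6	3
age_lt50	average	<20	32	17	11	5
age_lt50	average	<30	5	5	1	1
age_lt50	average	<40	2	0	2	4
age_lt50	average	>=40	0	0	0	3
age_lt50	hottest_spot	<10	0	1	2	0
age_lt50	hottest_spot	<20	14	10	1	0
age_lt50	hottest_spot	<30	22	11	2	1
age_lt50	hottest_spot	<40	19	7	6	4
age_lt50	hottest_spot	>=40	21	12	9	11
age_lt50	grade	1	24	9	2	1
age_lt50	grade	2	46	29	13	7
age_lt50	grade	3	6	3	5	8
age_lt50	combined	low	36	18	5	1
age_lt50	combined	high	40	23	15	15
age_ge50	hotspot	<10	4	4	3	1
age_ge50	hotspot	<20	12	3	0	0
age_ge50	hotspot	<30	14	3	3	2
age_ge50	hotspot	<40	6	2	3	5
age_ge50	hotspot	>=40	4	5	7	6
age_ge50	average	<10	27	10	5	2
age_ge50	average	<20	12	5	6	6
age_ge50	average	<30	1	2	4	2
age_ge50	average	<40	0	0	1	3
age_ge50	average	>=40	0	0	0	1
age_ge50	hottest_spot	<10	3	4	2	1
age_ge50	hottest_spot	<20	8	3	1	0
age_ge50	hottest_spot	<30	15	2	2	2
age_ge50	hottest_spot	<40	9	3	4	3
age_ge50	hottest_spot	>=40	5	5	7	8
age_ge50	grade	1	9	4	0	2
age_ge50	grade	2	29	13	11	7
age_ge50	grade	3	2	0	5	5
age_ge50	combined	low	23	8	3	2
age_ge50	combined	high	17	9	13	12
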