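# Published session summaries for the two control groups (transcribed study data).
# HRg/SDg are the group mean heart rate and its SD in the first 5-minute span (bpm);
# barriers is the dimensionless group statistic (mean A1 - mean A2) / mean A3;
# eduflow_percent is group flow as a percentage of the EduFlow scale maximum.
group	session	hrg	sdg	barriers	eduflow_percent
N5_1	2	77.82	6.47	-0.71	58.81
N5_1	3	98.03	6.86	-0.40	61.69
N5_1	4	85.49	6.13	-0.56	49.11
N5_1	5	96.55	6.22	-0.29	53.06
N5_1	6	84.69	7.04	-0.60	59.14
N5_1	7	88.02	6.92	-0.14	62.99
N5_1	8	84.18	6.93	-0.20	58.12
N5_1	9	85.37	6.99	-0.23	57.14
N6_1	2	76.55	6.53	-1.09	74.66
N6_1	3	74.10	6.74	-0.56	67.06
N6_1	4	76.20	7.18	-0.49	69.05
N6_1	5	77.71	6.29	-0.72	68.66
N6_1	6	73.67	6.50	-0.82	66.37
N6_1	7	84.76	6.52	-0.22	59.38
N6_1	8	81.99	6.48	-0.73	64.81
N6_1	9	86.56	7.11	-0.43	61.11
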