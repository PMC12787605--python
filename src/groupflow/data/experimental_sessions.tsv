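# Published session summaries for the two experimental groups (transcribed study data).
# Columns as in control_sessions.tsv, plus d1g (group mean cognitive-absorption sum,
# EduFlow D1, points) and the flow-zone label issued by the early-alert advisory system.
group	session	hrg	sdg	barriers	d1g	eduflow_percent	easfe_label
N5_2	1	94.33	7.33	-0.90	10.83	83.23	Low
N5_2	2	90.99	6.94	-0.64	12.64	78.36	Medium
N5_2	3	92.17	7.55	-0.26	10.40	81.61	Medium
N5_2	4	99.00	8.38	-0.66	11.63	82.23	Low
N5_2	5	94.75	6.05	-0.73	12.67	78.48	No Flow
N5_2	6	92.90	7.07	-0.80	13.82	77.88	Low
N5_2	7	90.12	6.32	-0.58	13.36	77.78	Medium
N6_2	1	86.02	4.90	-0.66	10.50	70.79	Medium
N6_2	2	83.82	5.76	-0.43	16.43	71.51	Medium
N6_2	3	90.18	6.78	-0.43	16.33	73.26	Medium
N6_2	4	85.10	6.94	-0.50	14.70	69.56	Medium
N6_2	5	90.72	5.13	-0.62	15.50	70.14	Medium
N6_2	6	83.12	5.34	-0.39	16.00	61.51	Medium
N6_2	7	85.99	6.52	-0.31	13.56	62.18	Medium
N6_2	8	88.56	6.20	-0.33	14.78	63.31	Medium
N6_2	9	91.23	8.07	-0.55	13.67	64.92	Medium
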