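# Published per-session group means and SDs of the perceived-balance dimension
# (FKS A3, 9-point Likert scale), transcribed study data. N5_* are the graphic-design
# cohort, N6_* the robotics cohort; _1 = control arm, _2 = experimental arm.
# The experimental design group (N5_2) has no sessions 8-9 (Roblox Studio lessons
# were not run in that group).
group	session	a3_mean	a3_sd
N5_1	1	4.92	0.515
N5_1	2	6.00	1.732
N5_1	3	5.14	1.657
N5_1	4	4.43	1.618
N5_1	5	5.27	1.009
N5_1	6	5.08	1.320
N5_1	7	4.57	1.158
N5_1	8	4.86	1.406
N5_1	9	5.38	1.261
N5_2	1	5.55	1.214
N5_2	2	6.00	1.789
N5_2	3	5.60	1.350
N5_2	4	5.38	1.261
N5_2	5	5.08	0.494
N5_2	6	5.00	0.426
N5_2	7	4.92	0.669
N6_1	1	4.43	1.512
N6_1	2	4.36	1.120
N6_1	3	4.67	1.155
N6_1	4	5.07	0.730
N6_1	5	4.55	1.968
N6_1	6	5.23	1.235
N6_1	7	5.31	0.855
N6_1	8	5.00	1.537
N6_1	9	5.08	1.084
N6_2	1	5.33	1.047
N6_2	2	4.79	0.802
N6_2	3	5.15	1.214
N6_2	4	5.20	0.414
N6_2	5	5.25	0.754
N6_2	6	5.44	0.527
N6_2	7	5.23	0.725
N6_2	8	5.27	0.905
N6_2	9	4.92	0.494
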