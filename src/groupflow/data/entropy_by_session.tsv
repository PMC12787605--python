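# Published per-session Shannon entropy H (bits) of the perceived-balance (A3)
# response distribution, transcribed study data. Raw response counts behind these
# H values were not published; only the per-group mean row is recomputable.
group	session	h_bits
N5_1	1	1.28
N5_1	2	2.58
N5_1	3	2.67
N5_1	4	2.67
N5_1	5	2.11
N5_1	6	2.44
N5_1	7	2.30
N5_1	8	2.53
N5_1	9	2.37
N5_2	1	2.32
N5_2	2	2.60
N5_2	3	2.42
N5_2	4	2.37
N5_2	5	1.23
N5_2	6	1.04
N5_2	7	1.59
N6_1	1	2.61
N6_1	2	2.25
N6_1	3	2.29
N6_1	4	1.70
N6_1	5	2.82
N6_1	6	2.36
N6_1	7	1.90
N6_1	8	2.61
N6_1	9	2.21
N6_2	1	2.16
N6_2	2	1.82
N6_2	3	2.34
N6_2	4	1.04
N6_2	5	1.74
N6_2	6	1.32
N6_2	7	1.69
N6_2	8	1.97
N6_2	9	1.23
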