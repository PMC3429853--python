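# loop penalties, dG37 kcal/mol; Jacobson-Stockmayer extrapolated anchors
# type	size	dG
hairpin	3	5.40
hairpin	4	5.71
hairpin	5	5.95
hairpin	6	6.15
hairpin	7	6.31
hairpin	8	6.46
hairpin	9	6.58
hairpin	10	6.70
hairpin	11	6.80
hairpin	12	6.90
hairpin	13	6.98
hairpin	14	7.06
hairpin	15	7.14
hairpin	16	7.21
hairpin	17	7.27
hairpin	18	7.33
hairpin	19	7.39
hairpin	20	7.45
hairpin	21	7.50
hairpin	22	7.55
hairpin	23	7.60
hairpin	24	7.64
hairpin	25	7.69
hairpin	26	7.73
hairpin	27	7.77
hairpin	28	7.81
hairpin	29	7.85
hairpin	30	7.88
bulge	1	3.80
bulge	2	4.55
bulge	3	4.98
bulge	4	5.30
bulge	5	5.54
bulge	6	5.73
bulge	7	5.90
bulge	8	6.04
bulge	9	6.17
bulge	10	6.28
bulge	11	6.39
bulge	12	6.48
bulge	13	6.57
bulge	14	6.65
bulge	15	6.72
bulge	16	6.79
bulge	17	6.86
bulge	18	6.92
bulge	19	6.98
bulge	20	7.03
bulge	21	7.08
bulge	22	7.13
bulge	23	7.18
bulge	24	7.23
bulge	25	7.27
bulge	26	7.31
bulge	27	7.35
bulge	28	7.39
bulge	29	7.43
bulge	30	7.47
internal	2	4.10
internal	3	4.54
internal	4	4.85
internal	5	5.09
internal	6	5.28
internal	7	5.45
internal	8	5.60
internal	9	5.72
internal	10	5.84
internal	11	5.94
internal	12	6.03
internal	13	6.12
internal	14	6.20
internal	15	6.27
internal	16	6.34
internal	17	6.41
internal	18	6.47
internal	19	6.53
internal	20	6.58
internal	21	6.64
internal	22	6.69
internal	23	6.73
internal	24	6.78
internal	25	6.82
internal	26	6.87
internal	27	6.91
internal	28	6.95
internal	29	6.98
internal	30	7.02
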