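id	rmt	depth_m1	depth_dlpfc
1	75	15.88	16.89
2	68	15.76	15.45
6	75	14.03	13.74
8	64	12.30	12.10
9	46	15.07	12.88
12	42	10.89	12.30
13	75	18.44	17.52
14	47	13.60	12.83
15	69	16.12	14.27
16	52	13.96	12.41
17	72	13.52	14.65
19	43	12.05	10.13
21	41	14.12	12.65
22	56	18.33	21.46
24	47	11.89	10.78
25	75	16.48	13.85
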