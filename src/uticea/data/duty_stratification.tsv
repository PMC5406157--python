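# Risk stratification counts per diagnostic strategy and confirmed UTI status,
# for the 2543 children not referred as very unwell (55 UTI, 2488 no UTI).
strategy	uti_status	lower	intermediate	higher
clinical_judgment	no_uti	2276	83	129
clinical_judgment	uti	24	9	22
duty_5pct	no_uti	2393	52	43
duty_5pct	uti	23	12	20
duty_10pct	no_uti	2271	122	95
duty_10pct	uti	16	7	32
duty_20pct	no_uti	2004	267	217
duty_20pct	uti	8	8	39
duty_ge6	no_uti	2395	82	11
duty_ge6	uti	31	17	7
duty_ge5	no_uti	2340	55	93
duty_ge5	uti	26	5	24
duty_ge4	no_uti	1946	394	148
duty_ge4	uti	11	15	29
duty_ge3	no_uti	1829	511	148
duty_ge3	uti	8	18	29
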