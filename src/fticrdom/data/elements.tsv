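# fticrdom element and isotope table, v1
# kind	symbol	value_da
element	C	12.0
element	H	1.007825032
element	O	15.994914622
element	N	14.003074005
element	P	30.973761998
element	S	31.972071174
constant	electron	0.000548580
isotope_shift	13C	1.003354835
isotope_shift	15N	0.997034894
isotope_shift	34S	1.995795836
isotope_shift	33S	0.999387736
isotope_shift	18O	2.004244991
isotope_shift	17O	1.004217134
isotope_shift	2H	1.006276746
constant	c13_abundance	0.0107
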