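chrX	0	4300000	p22.33	gneg
chrX	4300000	6000000	p22.32	gpos50
chrX	6000000	9500000	p22.31	gneg
chrX	9500000	17100000	p22.2	gpos50
chrX	17100000	19300000	p22.13	gneg
chrX	19300000	21900000	p22.12	gpos50
chrX	21900000	24900000	p22.11	gneg
chrX	24900000	29300000	p21.3	gpos100
chrX	29300000	31500000	p21.2	gneg
chrX	31500000	37600000	p21.1	gpos100
chrX	37600000	42400000	p11.4	gneg
chrX	42400000	46400000	p11.3	gpos75
chrX	46400000	49800000	p11.23	gneg
chrX	49800000	54800000	p11.22	gpos25
chrX	54800000	58100000	p11.21	gneg
chrX	58100000	60600000	p11.1	acen
chrX	60600000	63000000	q11.1	acen
chrX	63000000	64600000	q11.2	gneg
chrX	64600000	67800000	q12	gpos50
chrX	67800000	71800000	q13.1	gneg
chrX	71800000	73900000	q13.2	gpos50
chrX	73900000	76000000	q13.3	gneg
chrX	76000000	84600000	q21.1	gpos100
chrX	84600000	86200000	q21.2	gneg
chrX	86200000	91800000	q21.31	gpos100
chrX	91800000	93500000	q21.32	gneg
chrX	93500000	99100000	q21.33	gpos75
chrX	99100000	103300000	q22.1	gneg
chrX	103300000	104500000	q22.2	gpos50
chrX	104500000	110400000	q22.3	gneg
chrX	110400000	116700000	q23	gpos75
chrX	116700000	120800000	q24	gneg
chrX	120800000	128700000	q25	gpos100
chrX	128700000	130400000	q26.1	gneg
chrX	130400000	133600000	q26.2	gpos25
chrX	133600000	138000000	q26.3	gneg
chrX	138000000	140300000	q27.1	gpos75
chrX	140300000	142100000	q27.2	gneg
chrX	142100000	147100000	q27.3	gpos100
chrX	147100000	155270560	q28	gneg
chrY	0	2500000	p11.32	gneg
chrY	2500000	3000000	p11.31	gpos50
chrY	3000000	11600000	p11.2	gneg
chrY	11600000	12500000	p11.1	acen
chrY	12500000	13400000	q11.1	acen
chrY	13400000	15100000	q11.21	gneg
chrY	15100000	19800000	q11.221	gpos50
chrY	19800000	22100000	q11.222	gneg
chrY	22100000	26200000	q11.223	gpos50
chrY	26200000	28800000	q11.23	gneg
chrY	28800000	59373566	q12	gvar
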