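property_id	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
polar_requirement	7.0	9.1	10.0	13.0	4.8	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5.0	6.6	7.5	6.6	5.2	5.4	5.6
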