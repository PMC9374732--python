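biosample	rep_lab_id	rep_isb	rep_name	rep_species	rep_sex	cor_lab_id	cor_isb	cor_name	cor_species	cor_sex	xy_ratio
SAMN00007164	KB5404	590	Billy	B	F	KB5404	356	Dinah	B	F	4.556
SAMN00007165	KB4204	364	Dolly	B	M	KB4204	590	Billy	B	M	0.506
SAMN00007166	KB5406	356	Dinah	B	F	KB5406	364	Dolly	B	F	5.015
SAMN00007167	KB5405	360	Dennis	B	M	KB5405	360	Dennis	B	M	0.547
SAMN00007168	KB5543	990	Louis	B	M	.	990	Louis	B	M	0.464
SAMN00007169	KB5883	550	Sibu	S	M	KB5883	1600	Likoe	S	M	0.444
SAMN00007170	KB9528	732	Baldy	S	M	KB9258	695	Bubbles	T	F	4.170
SAMN00007171	KB4661	695	Bubbles	S	M	KB4661	732	Baldy	S	M	0.432
SAMN00007172	KB4361	1600	Likoe	S	F	KB4361	53	Doris	S	F	4.625
SAMN00007173	SB550	53	Doris	S	F	.	550	Sibu	S	F	4.264
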