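biosample	relative_isb	relative_name	relationship	delta0	delta1	delta2	phi_exp	phi_hat
SAMN00007165	3572	Batari	granddaughter	0.655	0.226	0.119	0.125	0.116
SAMN00007166	1387	Dumplin	daughter	0.432	0.376	0.192	0.250	0.190
SAMN00007167	1387	Dumplin	daughter	0.411	0.530	0.060	0.250	0.162
SAMN00007168	3619	Max	grandson	0.823	0.025	0.152	0.125	0.082
SAMN00007169	3351	Menari	great-granddaughter	0.971	0.000	0.221	0.063	0.063
SAMN00007170	1980	Bella	daughter	0.200	0.632	0.168	0.250	0.242
SAMN00007170	1773	Oliver	son	0.186	0.696	0.118	0.250	0.233
SAMN00007170	3450	Nairi/Nadira	granddaughter	0.771	0.229	0.000	0.125	0.036
SAMN00007173	2069	Tengku	son	0.313	0.390	0.298	0.250	0.246
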