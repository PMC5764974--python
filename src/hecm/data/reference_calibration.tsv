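analyte	slope	intercept	range_low_ug_ml	range_high_ug_ml	r2	lod_ug_ml	loq_ug_ml	content_pct_s22	content_pct_s23	content_pct_s24
DIOB	10185812.57	367287.09	78.77	2520.60	0.9993	5.08	13.10	6.60	4.57	12.60
EEA	10924180.01	-4967.65	20.55	657.60	0.9998	3.91	15.39	7.06	6.45	1.16
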