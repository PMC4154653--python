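species	replicon	orf_index	strand	subunit_label
alpha_natpase	chr	0	+	IB
alpha_natpase	chr	1	+	IE
alpha_natpase	chr	2	+	I
alpha_natpase	chr	3	+	R
alpha_natpase	chr	4	+	0A
alpha_natpase	chr	5	+	0C
alpha_natpase	chr	6	+	0B
alpha_natpase	chr	7	+	IA
alpha_natpase	chr	8	+	IG
delta_natpase	chr	0	+	IB
delta_natpase	chr	1	+	IE
delta_natpase	chr	2	+	I
delta_natpase	chr	3	+	R
delta_natpase	chr	4	+	0A
delta_natpase	chr	5	+	0C
delta_natpase	chr	6	+	0B
delta_natpase	chr	7	+	IA
delta_natpase	chr	8	+	IG
bacteroides_fragilis_like	chr	0	+	IB
bacteroides_fragilis_like	chr	1	+	IE
bacteroides_fragilis_like	chr	2	+	I
bacteroides_fragilis_like	chr	3	+	0A
bacteroides_fragilis_like	chr	4	+	0C
bacteroides_fragilis_like	chr	5	+	0B
bacteroides_fragilis_like	chr	6	+	IA
bacteroides_fragilis_like	chr	7	+	IG
split_natpase_no_r	chr	0	+	IB
split_natpase_no_r	chr	1	+	IE
split_natpase_no_r	chr	1001	+	I
split_natpase_no_r	chr	1002	+	0A
split_natpase_no_r	chr	1003	+	0C
split_natpase_no_r	chr	1004	+	0B
split_natpase_no_r	chr	1005	+	IA
split_natpase_no_r	chr	1006	+	IG
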