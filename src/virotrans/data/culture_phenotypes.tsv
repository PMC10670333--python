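culture_id	cd50_pfu_per_cell	annv_pi_minus_pct	annv_pi_plus_pct	cell_index	culture_kind
BR1	6.3e-3	31.3	57.7	11.12	patient_derived
BR3	2.4e-2	23.6	6.92	3.43	patient_derived
BR4	6.5e-1	12.8	5.42	0.94	patient_derived
BR5	5.2e-1	13.1	17.7	3.45	patient_derived
NB	5.8	5.7	0.74	1.07	normal
U87	1.2e-1	18.2	8.31	1.39	immortalized
U343	6.5e-2	35.9	5.63	2.59	immortalized
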