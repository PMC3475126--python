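guild_id	functional_group	uses_don	vmax_lo	vmax_hi	km_lo	km_hi	mu_lo	mu_hi	kmo2_lo	kmo2_hi	yield_lo	yield_hi	temp_lo	temp_hi	ki_nh3	phylogeny
AOB(1)	AOB	no	0.38	1.1	30	61	0.02	0.09	6.9	17.6	0.04	0.08	290	295	4000	Nitrosomonas europaea
AOB(2)	AOB	no	0.24	0.24	14	43	0.01	0.06	3.6	12.4	0.08	0.09	287	299	4000	Nitrosomonas communis
AOB(3)	AOB	yes	0.4	0.9	19	46	0.04	0.04	4.2	14	0.06	0.06	287	299	4000	Nitrosomonas nitrosa
AOB(4)	AOB	yes	0.4	0.8	1.9	4.2	0.06	0.08	1.4	4.7	0.02	0.05	287	299	4000	Nitrosomonas oligotropha
AOB(5)	AOB	yes	1.0	1.04	50	52	0.018	0.018	11	23	0.04	0.07	287	299	4000	Nitrosomonas marina
AOB(6)	AOB	yes	0.8	1.2	42	59	0.04	0.04	11	23	0.02	0.03	275	286	4000	Nitrosomonas cryotolerans
AOB(7)	AOB	yes	0.42	0.9	1.4	11	0.07	0.08	0.7	1.2	0.06	0.06	285	299	4000	Nitrosospira spp.
AOA	AOA	unknown	0.4	0.8	0.01	0.02	0.09	0.11	0.015	0.015	0.05	0.05	285	299	0.5	Nitrosopumilus maritimus
NOB(1)	NOB	no	0.8	1.9	4	10	0.3	0.7	40	80	0.01	0.03	285	295		Nitrospina spp.
NOB(2)	NOB	no	2	3.2	45	260	0.8	1.0	60	120	0.04	0.07	275	302		Nitrobacter spp.
NOB(3)	NOB	no	0.4	4	24	120	0.5	0.7	35	70	0.03	0.06	273	284		uncharacterized NOB
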