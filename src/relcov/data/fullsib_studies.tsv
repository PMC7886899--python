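trait	study	n_pairs	c2	c2_se	h2	h2_se
height	ukb	19954	0.23	0.06	0.60	0.12
height	young2018	64847	0.07	0.05	0.68	0.10
height	hemani2013	20240	0.08	0.07	0.69	0.14
bmi	ukb	19885	-0.13	0.08	0.81	0.17
bmi	young2018	56461	0.08	0.06	0.39	0.12
bmi	hemani2013	20240	0.10	0.08	0.42	0.17
ea	ukb	19736	0.22	0.08	0.14	0.16
ea	young2018	32542	0.16	0.07	0.40	0.15
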