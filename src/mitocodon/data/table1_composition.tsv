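species	length_bp	A	C	G	T	AT	GC	at_skew	gc_skew
Pseudobagrus albomarginatus	16533	31.78	26.35	14.86	27.00	58.78	41.21	0.08132	-0.27882
Pseudobagrus brachyrhabdion	16532	31.02	26.39	15.55	27.05	58.07	41.94	0.06837	-0.25846
Pseudobagrus brevicaudatus	16533	31.65	26.59	14.95	26.82	58.47	41.54	0.08261	-0.28021
Pseudobagrus brevicorpus	16526	30.82	27.99	15.45	25.74	56.56	43.44	0.08982	-0.28867
Pseudobagrus emarginatus	16534	31.55	26.79	14.91	26.75	58.30	41.70	0.08233	-0.28489
Pseudobagrus gracilis	16533	31.03	26.31	15.52	27.14	58.17	41.83	0.06687	-0.25795
Pseudobagrus koreanus	16532	30.96	27.60	15.30	26.14	57.10	42.90	0.08441	-0.28671
Pseudobagrus medianalis	16647	30.91	28.00	15.38	25.70	56.61	43.38	0.09203	-0.29092
Pseudobagrus ondon	16534	31.06	27.97	15.24	25.72	56.78	43.21	0.09405	-0.29461
Pseudobagrus pratti	16533	31.55	26.78	14.91	26.76	58.31	41.69	0.08215	-0.28472
Pseudobagrus tenuis	16535	31.76	26.38	14.88	26.99	58.75	41.26	0.08119	-0.27872
Pseudobagrus tokiensis	16529	30.91	27.85	15.33	25.91	56.82	43.18	0.088	-0.28995
Pseudobagrus trilineatus	16535	31.56	27.13	14.83	26.48	58.04	41.96	0.08753	-0.29314
Pseudobagrus truncatus	16533	31.56	26.78	14.93	26.73	58.29	41.71	0.08286	-0.2841
Pseudobagrus ussuriensis	16536	31.79	26.50	14.87	26.84	58.63	41.37	0.08443	-0.28112
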