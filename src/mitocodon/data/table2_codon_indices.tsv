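species	CAI	ENC	GC3s	GC	GC1	GC2	GC3
Pseudobagrus albomarginatus	0.169	55.950	0.429	0.430	50.51%	40.58%	31.68%
Pseudobagrus brachyrhabdion	0.161	55.740	0.426	0.437	51.03%	40.73%	34.20%
Pseudobagrus brevicaudatus	0.165	55.020	0.408	0.430	50.54%	40.53%	32.52%
Pseudobagrus brevicorpus	0.158	55.840	0.429	0.449	51.00%	40.76%	39.34%
Pseudobagrus emarginatus	0.159	56.940	0.437	0.451	50.59%	40.45%	33.83%
Pseudobagrus gracilis	0.154	55.320	0.400	0.435	50.91%	40.58%	33.94%
Pseudobagrus koreanus	0.162	55.720	0.430	0.447	50.81%	40.81%	37.76%
Pseudobagrus medianalis	0.150	55.070	0.420	0.448	51.23%	40.73%	38.92%
Pseudobagrus ondon	0.166	54.990	0.421	0.434	51.19%	40.63%	38.61%
Pseudobagrus pratti	0.167	55.280	0.421	0.434	50.75%	40.45%	33.70%
Pseudobagrus tenuis	0.170	55.950	0.432	0.430	50.49%	40.56%	31.86%
Pseudobagrus tokiensis	0.164	55.660	0.439	0.450	51.33%	40.89%	38.58%
Pseudobagrus trilineatus	0.161	53.960	0.412	0.434	49.79%	40.41%	35.61%
Pseudobagrus truncatus	0.168	55.300	0.423	0.434	50.72%	40.48%	33.86%
Pseudobagrus ussuriensis	0.147	53.460	0.368	0.425	50.67%	40.43%	32.13%
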