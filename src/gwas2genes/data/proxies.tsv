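rsid	ld_block_bp	n_snps_ld	proxy_other	r2_other	proxy_biopsy	r2_biopsy	proxy_brush	r2_brush	proxy_nasal	r2_nasal
rs61816761	988882	20	rs61816766	0.50	rs61816764	0.21				
rs7523907	41739	56	rs3108155	0.83	rs2056625	0.73				
rs12479210	458394	578			rs2270298	0.47	rs2241116	0.46		
rs34290285	69955	157			rs34077392	0.43				
rs560026225	622215	150	rs72687036	0.66						
rs1837253	71462	29								
rs1438673	227233	353			rs2289277	0.73			rs7524421	1.00
rs3749833	526932	325							rs11748326	0.76
rs1986009	365939	239	rs12652920	1.00	rs12652920	1.0	rs4705952	0.21		
rs9273410	554975	5739								
rs776111176	574227	1447	rs3997872	0.82						
rs367983479	244383	191	rs1504215	0.85	rs4142967	0.56				
rs71266076	175000	206	rs7824993	0.81						
rs144829310	496605	234			rs1929996	0.43				
rs10905284	67858	96								
rs11603634	146648	187			rs11602802	0.40				
rs7936312	316410	277	rs7936323	0.96						
rs7305461	315101	120	rs1131017	0.75						
rs703816	284371	165			rs167769	0.82				
rs10519068	108343	123			rs2279292	0.91	rs2279296	0.13	rs2279296	0.13
rs72743461	30796	45					rs10152544	0.30	rs10152544	0.30
rs7203459	429719	435			rs12919828	0.98	rs6498135	0.30		
rs2941522	805248	896			rs907091	0.96				
rs112502960	270023	370	rs62076439	1.00						
rs61840192	201710	249	rs1031163	1.00						
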