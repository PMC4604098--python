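gene	start	end	matched
AT1G01580	2660	2667	GTATATTC
AT1G01580	2701	2708	GTATATTC
AT1G18910	134	141	GGATATCC
AT1G18910	359	366	GTATATAC
AT1G18910	1311	1318	GTATATGC
AT1G24320	2052	2059	GCATATCC
AT1G48300	1167	1174	GCATATTC
AT2G02310	645	652	GCATATAC
AT3G12900	445	452	GTATATTC
AT3G18290	129	136	GTATATAC
AT3G18290	703	710	GCATATGC
AT3G56980	153	160	GTATATGC
AT3G56980	2484	2491	GTATATGC
AT3G56980	2484	2491	GTATATGC
AT4G00910	2514	2521	GTATATGC
AT4G19690	838	845	GAATATCC
AT4G22980	1641	1648	GAATATAC
AT5G02780	369	376	GAATATGC
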