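prey	Killer whales	Sea lions	Pink cusk-eel	Southern hake	Seabirds	Red cod	Penguins	Salmon	Long-tailed hake	Patagonian robalo	Benthic fish	Humpback whales	Cephalopods	Fuegian sprat	Squat lobster	Amphipods	Benthos	Euphausiids	Mesozooplankton	flow_to_detritus
Killer whales	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	0.109
Sea lions	0.012	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	1.137
Pink cusk-eel	0.005	0.052	-	-	0.000	-	-	-	0.004	-	-	-	-	-	-	-	-	-	-	0.043
Southern hake	0.111	0.056	0.025	-	0.021	0.036	0.052	-	0.263	-	-	-	-	-	-	-	-	-	-	0.829
Seabirds	0.001	-	-	-	0.000	-	-	-	-	-	-	-	-	-	-	-	-	-	-	0.036
Red cod	0.028	0.028	0.000	0.028	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	0.092
Penguins	0.001	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	1.188
Salmon	0.044	0.713	0.015	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	0.467
Long-tailed hake	0.111	0.768	0.025	1.047	0.021	0.033	-	-	0.037	-	-	-	-	-	-	-	-	-	-	1.094
Patagonian robalo	-	0.321	0.019	-	0.000	-	0.006	0.435	-	-	-	-	-	-	-	-	-	-	-	0.505
Benthic fish	-	0.518	0.029	0.445	-	0.073	0.027	0.199	0.042	0.511	-	-	-	-	-	-	-	-	-	0.976
Humpback whales	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	-	5.189
Cephalopods	0.129	0.768	0.011	0.364	0.021	0.018	1.947	0.319	5.636	-	0.939	-	0.294	-	-	-	0.351	-	-	8.085
Fuegian sprat	0.064	1.427	0.022	0.946	0.060	0.054	2.381	0.348	8.120	-	-	6.105	-	-	-	-	-	-	-	13.430
Squat lobster	-	0.865	0.019	0.475	0.031	0.148	1.409	0.272	2.775	0.184	0.469	7.869	0.634	-	-	-	-	-	-	31.950
Amphipods	-	-	0.007	-	-	0.000	-	-	8.767	-	1.408	2.931	11.740	6.283	-	-	5.901	-	-	29.080
Benthos	-	-	0.019	0.475	-	0.044	-	0.723	10.690	1.789	1.971	-	8.179	-	0.159	-	0.637	1.073	-	22.950
Euphausiids	-	-	0.000	0.222	0.021	0.000	-	-	5.821	-	-	6.701	4.491	1.336	-	-	-	-	-	20.740
Mesozooplankton	-	-	0.011	0.004	-	-	-	-	-	-	-	-	14.540	42.520	53.940	48.320	12.960	17.040	-	170.800
Phytoplankton	-	-	-	-	-	-	-	-	-	-	-	-	-	15.940	52.360	95.190	-	84.670	685.2	1518.000
Detritus	-	-	-	-	-	-	-	-	-	-	-	-	-	-	52.360	-	93.610	-	159.2	-
Import	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
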