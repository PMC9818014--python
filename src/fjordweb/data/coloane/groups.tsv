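name	role	biomass	pb	qb	ee	landings
Killer whales	consumer	0.065	0.118	7.760		0
Sea lions	consumer	0.189	0.238	29.180		0
Pink cusk-eel	consumer	0.101	0.680	2.000		0.005
Southern hake	consumer	1.931	0.310	2.074		0.005
Seabirds	consumer	0.029	0.047	6.104		0
Red cod	consumer	0.116	0.828	3.500		0.001
Penguins	consumer	0.100	0.240	58.230		0
Salmon	consumer		2.210	6.500	0.990	0
Long-tailed hake	consumer	3.731	1.220	11.300		0.003
Patagonian robalo	consumer		1.112	3.500	0.990	0
Benthic fish	consumer		1.560	4.010	0.990	0
Humpback whales	consumer	3.367	0.139	7.011		0
Cephalopods	consumer		3.500	12.800	0.990	0
Fuegian sprat	consumer		3.000	9.251	0.990	0
Squat lobster	consumer		1.330	11.600	0.990	0
Amphipods	consumer		7.300	28.000	0.990	0
Benthos	consumer		2.700	11.640	0.990	0.290
Euphausiids	consumer		2.960	16.200	0.990	0
Mesozooplankton	consumer		35.000	154.500	0.990	0
Phytoplankton	producer	12.430	197.200			0
Detritus	detritus					0
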