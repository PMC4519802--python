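feature	concentration_only	concentration_binding
Intercept	2.725	3.313
hsa-miR-105-3p	-0.125	-0.196
hsa-miR-122-3p		0.022
hsa-miR-124-3p		0.003
hsa-miR-126-3p		0.045
hsa-miR-1972	-0.003	-0.054
hsa-miR-28-5p	-0.316	-0.682
hsa-miR-30b-5p	-0.008
hsa-miR-363-3p	-0.141	-0.009
hsa-miR-424-5p	-0.069
hsa-miR-486-5p	0.083	0.212
hsa-miR-495	-0.045	-0.028
hsa-miR-548o-3p	-0.055
hsa-miR-122-5p X Women		0.007
hsa-miR-192-5p X Women	0.033	0.03
hsa-miR-200c-3p X Women		0.07
hsa-miR-548o-3p X Women	-0.296	-0.498
hsa-miR-720 X Women	0.059	0.018
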