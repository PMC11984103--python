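food_component	compound_id	mmol_per_g
apple	fru	1.5
apple	pectin	0.2
apple	protein	0.02
banana	starch	0.8
banana	fru	0.8
banana	protein	0.03
bread	starch	2.3
bread	protein	0.1
bread	lipid	0.03
cabbage	xyl	0.8
cabbage	glc	0.4
cabbage	protein	0.08
chicken	protein	1.0
chicken	lipid	0.5
eggplant	xyl	0.6
eggplant	fru	0.4
eggplant	protein	0.05
mince	protein	1.0
mince	lipid	0.9
onion	fru	1.2
onion	glc	0.5
onion	protein	0.04
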