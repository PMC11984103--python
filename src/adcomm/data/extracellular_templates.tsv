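enzyme_id	reaction_id	stoichiometry	reversible	products	name_
EC3.2.1.1	amylase	starch:-1;h2o:-2;glc:3	False	glc	extracellular amylase
EC3.2.1.67	exopolygalacturonase	pectin:-1;h2o:-2;galur:3	False	galur	pectate hydrolysis
EC3.4.21.x	protease	protein:-1;h2o:-1;ala:1;glu:1	False	ala	generic protease
EC3.1.1.3	lipase	lipid:-1;h2o:-3;glyc:1;oct:3	False	oct	generic lipase
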