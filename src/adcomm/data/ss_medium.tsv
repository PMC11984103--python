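compound_id	max_uptake_mmol_gVS_h
protein	0.08
lipid	0.03
prop	0.25
ac	0.15
gal	0.25
man	0.2
ara	0.15
rib	0.15
xyl	0.1
nh3	0.6
co2	1.5
h2o	1000
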