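compound_id	molecule_class
starch	carbohydrate
mal	carbohydrate
glc	carbohydrate
fru	carbohydrate
man	carbohydrate
gal	carbohydrate
xyl	carbohydrate
ara	carbohydrate
rib	carbohydrate
pectin	carbohydrate
galur	carbohydrate
protein	protein
ala	protein
glu	protein
lipid	lipid
glyc	lipid
oct	lipid
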