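# units: ha
# Land title type by (a) forest system and (b) modelled oil-palm suitability
# (full_stand = suitable, up25 = unsuitable) over the unprotected forest.
# Printed per-column totals (each section): 9497, 9732, 3936, 7009.
section,category,NT,CL,state_demarcated,state_undemarcated
forest_system,mangrove,1016,147,321,4179
forest_system,seasonally_flooded,3635,4235,1110,1563
forest_system,lowland_dry,2934,3917,1747,1017
forest_system,mixed_degraded,1912,1433,758,250
suitability,full_stand,3665,3952,1723,1003
suitability,up25,5832,5780,2213,6006
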