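# units: ha
# Forest systems and types of the study floodplain with flooding period and
# extents from the operational habitat classification.
# Printed "Sum of hectares" row (column-misaligned in the source): 251400, 436295, 30173.
# Recomputed column sums: total 251400, protected 221229, unprotected 30171.
forest_system,forest_type,flooding_period,total_ha,protected_ha,unprotected_ha
mangrove,beach_forest,tidal,5327,4672,655
mangrove,mangrove_forest,tidal,12863,12357,506
mangrove,nipah_palm_forest,tidal,26618,25399,1219
mangrove,transitional_forest,semi_tidal,13849,10567,3282
seasonally_flooded,freshwater_swamp_forest,gt_6_months,22284,16721,5563
seasonally_flooded,seasonal_freshwater_swamp_forest,3_6_months,12501,8253,4248
seasonally_flooded,peat_swamp_forest,gt_6_months,2132,2102,30
seasonally_flooded,swamp,gt_9_months,2750,2048,702
lowland_dry,lowland_dry_forest,lt_3_months,39008,30693,8315
lowland_dry,lowland_dry_dipterocarp_forest,never_rarely,101878,100866,1012
lowland_dry,limestone_forest,never_rarely,1679,1392,287
mixed_degraded,severely_degraded,varied,10511,6159,4352
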