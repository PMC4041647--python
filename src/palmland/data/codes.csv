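# Integer category codes used by every categorical raster layer.
layer,code,label
soil,1,unsuitable
soil,2,marginal
soil,3,suitable
soil,4,very_suitable
forest_system,1,mangrove
forest_system,2,seasonally_flooded
forest_system,3,lowland_dry
forest_system,4,mixed_degraded
forest_system,5,non_forest
titles,1,NT
titles,2,CL
titles,3,state_demarcated
titles,4,state_undemarcated
productivity,0,full_stand
productivity,1,redundant
suitability,0,full_stand
suitability,1,redundant
river,0,land
river,1,river
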