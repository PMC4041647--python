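# units: ha
# Land title types, extent and unique demarcated titles over the unprotected forest.
# Printed TOTAL row: 30173 ha, 1338 titles. Recomputed area sum: 30175 ha.
# n_titles -1 marks "not applicable" (undemarcated land has no titles).
title_type,area_ha,n_titles
NT,9497,1175
CL,9732,163
state_demarcated,3937,104
state_undemarcated,7009,-1
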