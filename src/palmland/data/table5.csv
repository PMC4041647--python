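# units: ha
# Oil-palm age and productivity classes by land title type.
# Printed totals: area 250617; columns NT 70945, CL 174698, state 4974.
# total_ha is the printed per-class total (up75 prints 28081 vs cell sum 28082).
palm_class,total_ha,nt_ha,cl_ha,state_ha
cleared,3290,1729,1218,343
planted_out,4030,960,2520,550
young_prime_full_stand,191832,49328,140157,2347
up75,28081,10959,16563,560
up50,7575,3489,3754,332
up25,15810,4481,10486,843
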