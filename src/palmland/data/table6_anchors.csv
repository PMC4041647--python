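# units: USD/ha/yr (annualized 25-year NPV at the stated discount rate)
# Printed class-endpoint NPVs of the main (11%) economic models.
class,capacity,rate,npv_annualized
full_stand,1.00,0.11,637
full_stand,0.76,0.11,413
up75,0.75,0.11,403
up75,0.51,0.11,179
up50,0.50,0.11,169
up50,0.26,0.11,-55
up25,0.25,0.11,-65
up25,0.00,0.11,-299
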