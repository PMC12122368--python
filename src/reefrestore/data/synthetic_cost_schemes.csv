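technique,low_usd_per_ha,median_usd_per_ha,high_usd_per_ha
coral_gardening,6000,28200,1200000
transplantation,10000,160000,20000000
artificial_reef,20000,1000000,143000000
larval_enhancement,30000,400000,50000000
all_techniques,6000,400000,143000000
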