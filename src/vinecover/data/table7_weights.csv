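criterion,in_row,inter_row_annual,inter_row_perennial
dry_biomass,0.034,0.067,0.070
ground_coverage,0.060,0.125,0.148
fruiting_zone_interference,0.307,N/A,N/A
invasiveness_risk,0.432,0.596,0.572
pest_sensitivity,0.129,0.115,0.123
drought_tolerance,0.026,0.013,0.033
winter_hardiness,0.011,0.039,0.011
traffic_tolerance,N/A,0.045,0.044
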