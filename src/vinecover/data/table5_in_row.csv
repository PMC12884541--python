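life_cycle,name,biomass_cff,biomass_kow,coverage_cff,coverage_kow,fruiting_zone_interference,invasiveness_risk,pest_sensitivity,drought_tolerance,winter_hardiness
annual,Winfred brassica,2860,7343,2.1,2.6,1,1,2,1,4
annual,Buckwheat,2186,1514,3.6,2.6,2,2,1,1,1
annual,Field pea,2113,1550,2.9,2.8,3,1,2,2,2
annual,White mustard,994,762,1.7,1.5,2,3,2,1,4
annual,Phacelia,1587,847,2.3,1.6,2,1,1,1,1
annual,Purple top turnip,3249,3107,3.9,3.4,1,1,2,1,2
annual,Spring lentil,1942,1917,2.9,2.7,1,1,1,2,2
perennial,Crescendo Ladino white clover,3046,3571,2.1,1.7,1,1,2,2,5
perennial,Buffalo grass,1,157,1.0,1.5,1,1,1,3,3
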