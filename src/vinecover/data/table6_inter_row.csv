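life_cycle,name,biomass_cff,biomass_kow,coverage_cff,coverage_kow,invasiveness_risk,pest_sensitivity,drought_tolerance,winter_hardiness,traffic_tolerance
annual,Balansa clover,3176,1263,0.8,1.7,1,2,2,7,1
annual,Berseem clover,1022,6253,0.6,3.9,1,1,1,4,1
annual,Persian clover,1316,1750,1.1,1.7,1,1,1,3,1
annual,Crimson clover,1701,1822,1.4,3.4,1,1,1,3,1
annual,Alsike clover,2678,1678,0.6,1.8,1,2,2,4,1
annual,Hairy vetch + Cereal rye,7891,6512,3.0,2.8,3,2,2,6,2
annual,Field pea + Cereal rye,4151,8579,2.9,3.3,1,2,2,2,2
perennial,Crested wheatgrass + Pubescent wheatgrass,1124,1323,0.7,1.5,1,1,3,6,2
perennial,Indian ricegrass + Buckwheat,2037,1668,2.6,3.3,2,1,1,2,1
perennial,Blue grama,491,249,0.8,2,1,1,3,3,2
perennial,Western wheatgrass,592,911,0.6,1.4,2,1,3,6,2
perennial,Tall fescue + Red fescue + Sheep fescue,2215,1704,1.0,1.6,1,1,2,6,2
perennial,Perennial ryegrass + Tillage radish,6679,4515,2.6,3.5,1,1,1,4,2
perennial,Canada blue grass,455,368,0.6,1,2,1,2,5,2
perennial,Birdsfoot trefoil + Western wheatgrass,891,1140,0.7,2,2,1,2,6,2
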