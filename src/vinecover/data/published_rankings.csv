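site,position,life_cycle,name,rc
CFF,in_row,annual,Spring lentil,0.96
CFF,in_row,annual,Purple top turnip,0.89
CFF,in_row,annual,Winfred brassica,0.88
CFF,in_row,annual,Phacelia,0.77
CFF,in_row,annual,Field pea,0.61
CFF,in_row,annual,Buckwheat,0.51
CFF,in_row,annual,White mustard,0.23
CFF,in_row,perennial,Crescendo Ladino white clover,0.86
CFF,in_row,perennial,Buffalo grass,0.14
CFF,inter_row,annual,Field pea + Cereal rye,0.89
CFF,inter_row,annual,Crimson clover,0.83
CFF,inter_row,annual,Persian clover,0.82
CFF,inter_row,annual,Balansa clover,0.81
CFF,inter_row,annual,Alsike clover,0.80
CFF,inter_row,annual,Berseem clover,0.79
CFF,inter_row,annual,Hairy vetch + Cereal rye,0.18
CFF,inter_row,perennial,Perennial ryegrass + Tillage radish,0.94
CFF,inter_row,perennial,Tall fescue + Red fescue + Sheep fescue,0.65
CFF,inter_row,perennial,Crested wheatgrass + Pubescent wheatgrass,0.60
CFF,inter_row,perennial,Blue grama,0.60
CFF,inter_row,perennial,Indian ricegrass + Buckwheat,0.35
CFF,inter_row,perennial,Western wheatgrass,0.08
CFF,inter_row,perennial,Birdsfoot trefoil + Western wheatgrass,0.07
CFF,inter_row,perennial,Canada blue grass,0.06
KOW,in_row,annual,Spring lentil,0.91
KOW,in_row,annual,Winfred brassica,0.89
KOW,in_row,annual,Purple top turnip,0.87
KOW,in_row,annual,Phacelia,0.75
KOW,in_row,annual,Field pea,0.61
KOW,in_row,annual,Buckwheat,0.50
KOW,in_row,annual,White mustard,0.22
KOW,in_row,perennial,Crescendo Ladino white clover,0.82
KOW,in_row,perennial,Buffalo grass,0.18
KOW,inter_row,annual,Berseem clover,0.94
KOW,inter_row,annual,Field pea + Cereal rye,0.91
KOW,inter_row,annual,Crimson clover,0.88
KOW,inter_row,annual,Persian clover,0.85
KOW,inter_row,annual,Alsike clover,0.84
KOW,inter_row,annual,Balansa clover,0.84
KOW,inter_row,annual,Hairy vetch + Cereal rye,0.11
KOW,inter_row,perennial,Perennial ryegrass + Tillage radish,0.94
KOW,inter_row,perennial,Tall fescue + Red fescue + Sheep fescue,0.69
KOW,inter_row,perennial,Crested wheatgrass + Pubescent wheatgrass,0.67
KOW,inter_row,perennial,Blue grama,0.67
KOW,inter_row,perennial,Indian ricegrass + Buckwheat,0.30
KOW,inter_row,perennial,Birdsfoot trefoil + Western wheatgrass,0.17
KOW,inter_row,perennial,Western wheatgrass,0.11
KOW,inter_row,perennial,Canada blue grass,0.06
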