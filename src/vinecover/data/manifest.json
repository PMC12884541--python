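{
 "table5_in_row.csv": "bbaf56e6541e1602e08c18e821c4e52f3594aa89887e5ab73e39224191ca9449",
 "table6_inter_row.csv": "edb79e5b35d6a54d2de48c1f2af894116c9bcce26973187dc8d02051c69d7342",
 "table7_weights.csv": "a86d97fe958a8c8962699a70a4220f7d27e4fe8940e54c8f53d88cb6d4b84292",
 "published_rankings.csv": "a20d7b59efd6827033c41fd6889b2d126a4ff6010fc4993f4fa0837e1afcca27"
}
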