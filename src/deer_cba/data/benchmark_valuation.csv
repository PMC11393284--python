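class,meat_price_dkk_per_kg,weight_kg,recreational_dkk,browsing_dkk,traffic_constant_dkk,collision_probability
FC,20,38.3,3182,564,12423,0.02
FY,20,60.0,3391,898,19787,0.02
FA,20,73.9,3600,1094,24101,0.02
MC,20,40.7,3182,607,13364,0.02
MY,20,64.5,3746,950,20922,0.02
YS,20,113.6,5130,1677,36946,0.02
NS,20,131.6,6117,1939,42720,0.02
MS,20,118.7,7272,1818,40060,0.02
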