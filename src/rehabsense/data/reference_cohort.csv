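participant_id,tampa_chg,vas_chg,eq5d_chg,head_chg,left_chg,right_chg,short_participation
1016,-6,20,-4,0.054,0.077,0.095,0
1023,-6,53,-4,0.111,0.181,0.197,0
1025,7,-5,4,0.046,0.127,0.055,0
1037,-12,50,-4,0.066,0.067,0.113,0
1040,-2,5,0,-0.017,-0.055,-0.055,0
1042,-8,15,-1,0.088,0.185,0.283,0
1054,-4,-20,2,0.174,0.200,0.287,1
1059,-8,15,-3,0.069,0.253,0.049,0
1062,-11,60,-4,0.070,0.163,0.090,0
1072,-9,25,0,0.059,0.162,0.122,0
1076,-8,40,-6,0.074,0.158,0.182,0
1078,-7,-15,1,0.046,0.027,0.011,0
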