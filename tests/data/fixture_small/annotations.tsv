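synth_0000	CCCEECEECCCECEECECCCHCCCHCCCHCCCEHCCHEECHCCHCHCECHCHHECEHHCH	0.2603,0.8111,0.5027,0.0821,0.2273,0.1584,0.5954,0.6130,0.6960,0.4075,0.6965,0.2576,0.6531,0.0822,0.5380,0.6469,0.0709,0.5716,0.5594,0.7645,0.0819,0.4745,0.0166,0.3792,0.2302,0.7109,0.4803,0.0570,0.7464,0.1044,0.5349,0.4489,0.3658,0.6306,0.4442,0.4384,0.7853,0.6481,0.7542,0.3750,0.6541,0.7802,0.4271,0.0822,0.6196,0.6440,0.2290,0.7964,0.8273,0.5995,0.6055,0.6263,0.0429,0.5707,0.6086,0.2238,0.3981,0.7684,0.3767,0.7141
synth_0001	HCCEHEHCCCCHHEECCHECHEHCCCHHCEEHHHEHCHEEHCCCHEEEHHCHCCHEECCC	0.2065,0.6425,0.3690,0.1285,0.7450,0.1186,0.1441,0.5139,0.7675,0.1119,0.6720,0.0537,0.3162,0.7938,0.6932,0.7630,0.2554,0.5449,0.6161,0.7917,0.7854,0.4110,0.4998,0.3297,0.3252,0.4304,0.0962,0.6724,0.6348,0.3213,0.4215,0.6775,0.7129,0.2321,0.3909,0.4121,0.1439,0.5195,0.5321,0.8411,0.3770,0.4641,0.0636,0.0259,0.3430,0.3983,0.2284,0.7002,0.3314,0.4713,0.7174,0.3486,0.6215,0.6992,0.4098,0.1029,0.7532,0.5929,0.5042,0.6439
synth_0002	CCEHHHCECECECHCHHCCCCEHCHHEEHECECHHCCEHCCHCECCHCHHHCEEHCCHHC	0.6565,0.7276,0.1585,0.5323,0.3304,0.1701,0.2888,0.8304,0.2241,0.6722,0.6759,0.2029,0.1065,0.0161,0.6398,0.7382,0.0042,0.6749,0.4716,0.1585,0.4728,0.3546,0.1107,0.1436,0.4098,0.6702,0.6378,0.6243,0.0920,0.7604,0.1633,0.5742,0.1639,0.5877,0.7353,0.5014,0.1579,0.6786,0.6282,0.0921,0.0030,0.7680,0.8481,0.6232,0.4348,0.0652,0.0896,0.4569,0.6007,0.4084,0.0027,0.6545,0.2721,0.6153,0.1920,0.7975,0.3512,0.1607,0.5466,0.3605
synth_0003	EHCEECHEHCCCECHCCHCHCHCHHCEHCCHECECCCHHCECCEECCCCEEECECEHEHE	0.7367,0.6166,0.4093,0.5756,0.3934,0.4330,0.7406,0.7472,0.2952,0.1439,0.6235,0.2604,0.6439,0.3204,0.7044,0.6567,0.3703,0.4094,0.3811,0.2124,0.4132,0.0579,0.5636,0.0465,0.4076,0.4151,0.1654,0.2312,0.6728,0.7608,0.2424,0.3957,0.5778,0.1461,0.7269,0.4094,0.2760,0.3389,0.0949,0.0500,0.0669,0.3346,0.6951,0.3739,0.6940,0.1267,0.1917,0.6816,0.5598,0.2394,0.0515,0.4358,0.1257,0.6071,0.1418,0.3350,0.5104,0.4012,0.5096,0.1885
synth_0004	CHEHEHHHCHHCHHCECCHEHHEECEEECCCCEHCHCCCCHCHCCHHCCCCECEHCEHEE	0.3263,0.5737,0.0603,0.5374,0.7590,0.7245,0.3221,0.1414,0.6061,0.2510,0.7243,0.6522,0.6709,0.5985,0.5773,0.6455,0.6869,0.6834,0.0370,0.2755,0.0712,0.3775,0.7212,0.0672,0.0488,0.4218,0.7375,0.1774,0.7440,0.3814,0.1957,0.6361,0.1427,0.2500,0.1402,0.6528,0.6534,0.2096,0.7175,0.2296,0.3091,0.2105,0.5864,0.0007,0.4368,0.6813,0.5667,0.3838,0.6814,0.0158,0.1365,0.1129,0.2181,0.2977,0.7895,0.4469,0.3955,0.1115,0.5610,0.6053
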