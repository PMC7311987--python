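number,state,observed,analytic_predicted,analytic_sd,psa_predicted,psa_sd,bayes_predicted,bayes_sd
1,111111,1.0000,1.0000,0.0000,1.0000,0.0000,1.0000,0.0000
2,112543,0.6070,0.6648,0.0252,0.6648,0.0253,0.6386,0.0393
3,122211,0.6927,0.8588,0.0227,0.8590,0.0224,0.8384,0.0377
4,133132,0.5691,0.7503,0.0247,0.7500,0.0246,0.7212,0.0391
5,144144,0.6842,0.6896,0.0221,0.6897,0.0219,0.6718,0.0364
6,212453,0.6483,0.6396,0.0259,0.6393,0.0261,0.6406,0.0381
7,221535,0.6960,0.6174,0.0255,0.6171,0.0254,0.6247,0.0387
8,232111,0.7589,0.7550,0.0251,0.7550,0.0247,0.7283,0.0395
9,244313,0.6343,0.7085,0.0265,0.7083,0.0263,0.7023,0.0406
10,315515,0.5587,0.6295,0.0259,0.6294,0.0258,0.6342,0.0370
11,323153,0.5656,0.6623,0.0241,0.6621,0.0240,0.6427,0.0357
12,331244,0.7450,0.6620,0.0246,0.6621,0.0247,0.6515,0.0414
13,342322,0.7000,0.6615,0.0249,0.6616,0.0251,0.6518,0.0378
14,412152,0.5010,0.6481,0.0258,0.6483,0.0259,0.6413,0.0389
15,423333,0.5725,0.6678,0.0224,0.6676,0.0222,0.6630,0.0359
16,431443,0.6133,0.6323,0.0248,0.6323,0.0250,0.6123,0.0379
17,442343,0.6500,0.5800,0.0258,0.5803,0.0256,0.5835,0.0388
18,513531,0.5992,0.7132,0.0230,0.7129,0.0231,0.6760,0.0378
19,531635,0.4386,0.5280,0.0231,0.5275,0.0229,0.5249,0.0358
20,535422,0.4771,0.6108,0.0248,0.6107,0.0247,0.6031,0.0368
21,542345,0.6446,0.5484,0.0246,0.5489,0.0243,0.5453,0.0367
22,545122,0.5517,0.6461,0.0227,0.6463,0.0225,0.6417,0.0367
23,614434,0.6523,0.6212,0.0277,0.6208,0.0276,0.6252,0.0387
24,625141,0.7030,0.5254,0.0242,0.5258,0.0243,0.5481,0.0384
25,635255,0.4560,0.3921,0.0218,0.3922,0.0219,0.4328,0.0385
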