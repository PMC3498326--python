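fragment_class,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12,C13,C14,C15
f2,0.0015,0.0077,0.1259,0.0012,0.0015,0.0970,0.1355,0.1003,0.1036,0.1125,0.1100,0.1068,0.0960
f3,0.0014,0.0069,0.1217,0.0016,0.0014,0.0990,0.1312,0.1073,0.1026,0.1092,0.1152,0.1090,0.0934
f5,0.0027,0.1316,0.0876,0.0020,0.0020,0.1233,0.1246,0.1279,0.0036,0.1306,0.1384,0.0017,0.1238
f8,0.0018,0.0884,0.0896,0.0020,0.0006,0.1297,0.1317,0.1351,0.0037,0.1347,0.1519,0.0019,0.1288
f11,0.0103,0.0542,0.1248,0.0119,0.0120,0.0777,0.0301,0.0787,0.0894,0.1718,0.1716,0.0911,0.0763
f18,0.0013,0.1002,0.1000,0.0014,0.0014,0.1391,0.1237,0.1380,0.0022,0.1366,0.1350,0.0012,0.1198
f20,0.0109,0.0691,0.0698,0.0740,0.0713,0.0864,0.0863,0.0882,0.0891,0.0896,0.0894,0.0901,0.0858
f22,0.0068,0.0365,0.1052,0.0079,0.0080,0.0594,0.0229,0.0641,0.1193,0.1938,0.1922,0.1200,0.0638
f23,0.0058,0.0313,0.1016,0.0062,0.0066,0.0103,0.0187,0.0050,0.2090,0.2059,0.1926,0.2020,0.0049
f26,0.0020,0.0176,0.0966,0.0025,0.0022,0.0037,0.1563,0.0018,0.1822,0.1815,0.1749,0.1768,0.0020
f27,0.0023,0.0130,0.1083,0.0027,0.0025,0.0040,0.0656,0.0018,0.2025,0.2013,0.1939,0.2002,0.0018
f34,0.0112,0.0698,0.0712,0.0266,0.0739,0.0884,0.0871,0.0890,0.0955,0.1011,0.1025,0.0991,0.0846
f36,0.0110,0.0661,0.0729,0.0696,0.0835,0.0814,0.0779,0.0841,0.0890,0.0871,0.1069,0.0903,0.0803
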