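risk,outcome
0.02,1
0.0345,1
0.049,1
0.0635,1
0.078,1
0.0925,1
0.107,1
0.1215,1
0.136,1
0.1505,1
0.165,1
0.1795,1
0.194,1
0.2085,1
0.223,1
0.2375,1
0.252,1
0.2665,1
0.281,1
0.2955,1
0.31,1
0.3245,1
0.339,1
0.3535,1
0.368,1
0.3825,1
0.397,1
0.4115,1
0.426,1
0.4405,1
0.455,1
0.4695,1
0.484,1
0.4985,1
0.513,1
0.5275,1
0.542,1
0.5565,1
0.571,1
0.5855,1
0.6,1
0.008,1
0.015,1
0.02,0
0.021068,0
0.022136,0
0.023204,0
0.024272,0
0.02534,0
0.026408,0
0.027476,0
0.028544,0
0.029612,0
0.03068,0
0.031748,0
0.032816,0
0.033883,0
0.034951,0
0.036019,0
0.037087,0
0.038155,0
0.039223,0
0.040291,0
0.041359,0
0.042427,0
0.043495,0
0.044563,0
0.045631,0
0.046699,0
0.047767,0
0.048835,0
0.049903,0
0.050971,0
0.052039,0
0.053107,0
0.054175,0
0.055243,0
0.056311,0
0.057379,0
0.058447,0
0.059515,0
0.060583,0
0.06165,0
0.062718,0
0.063786,0
0.064854,0
0.065922,0
0.06699,0
0.068058,0
0.069126,0
0.070194,0
0.071262,0
0.07233,0
0.073398,0
0.074466,0
0.075534,0
0.076602,0
0.07767,0
0.078738,0
0.079806,0
0.080874,0
0.081942,0
0.08301,0
0.084078,0
0.085146,0
0.086214,0
0.087282,0
0.08835,0
0.089417,0
0.090485,0
0.091553,0
0.092621,0
0.093689,0
0.094757,0
0.095825,0
0.096893,0
0.097961,0
0.099029,0
0.100097,0
0.101165,0
0.102233,0
0.103301,0
0.104369,0
0.105437,0
0.106505,0
0.107573,0
0.108641,0
0.109709,0
0.110777,0
0.111845,0
0.112913,0
0.113981,0
0.115049,0
0.116117,0
0.117184,0
0.118252,0
0.11932,0
0.120388,0
0.121456,0
0.122524,0
0.123592,0
0.12466,0
0.125728,0
0.126796,0
0.127864,0
0.128932,0
0.13,0
0.131068,0
0.132136,0
0.133204,0
0.134272,0
0.13534,0
0.136408,0
0.137476,0
0.138544,0
0.139612,0
0.14068,0
0.141748,0
0.142816,0
0.143883,0
0.144951,0
0.146019,0
0.147087,0
0.148155,0
0.149223,0
0.150291,0
0.151359,0
0.152427,0
0.153495,0
0.154563,0
0.155631,0
0.156699,0
0.157767,0
0.158835,0
0.159903,0
0.160971,0
0.162039,0
0.163107,0
0.164175,0
0.165243,0
0.166311,0
0.167379,0
0.168447,0
0.169515,0
0.170583,0
0.17165,0
0.172718,0
0.173786,0
0.174854,0
0.175922,0
0.17699,0
0.178058,0
0.179126,0
0.180194,0
0.181262,0
0.18233,0
0.183398,0
0.184466,0
0.185534,0
0.186602,0
0.18767,0
0.188738,0
0.189806,0
0.190874,0
0.191942,0
0.19301,0
0.194078,0
0.195146,0
0.196214,0
0.197282,0
0.19835,0
0.199417,0
0.200485,0
0.201553,0
0.202621,0
0.203689,0
0.204757,0
0.205825,0
0.206893,0
0.207961,0
0.209029,0
0.210097,0
0.211165,0
0.212233,0
0.213301,0
0.214369,0
0.215437,0
0.216505,0
0.217573,0
0.218641,0
0.219709,0
0.220777,0
0.221845,0
0.222913,0
0.223981,0
0.225049,0
0.226117,0
0.227184,0
0.228252,0
0.22932,0
0.230388,0
0.231456,0
0.232524,0
0.233592,0
0.23466,0
0.235728,0
0.236796,0
0.237864,0
0.238932,0
0.24,0
0.241068,0
0.242136,0
0.243204,0
0.244272,0
0.24534,0
0.246408,0
0.247476,0
0.248544,0
0.249612,0
0.25068,0
0.251748,0
0.252816,0
0.253883,0
0.254951,0
0.256019,0
0.257087,0
0.258155,0
0.259223,0
0.260291,0
0.261359,0
0.262427,0
0.263495,0
0.264563,0
0.265631,0
0.266699,0
0.267767,0
0.268835,0
0.269903,0
0.270971,0
0.272039,0
0.273107,0
0.274175,0
0.275243,0
0.276311,0
0.277379,0
0.278447,0
0.279515,0
0.280583,0
0.28165,0
0.282718,0
0.283786,0
0.284854,0
0.285922,0
0.28699,0
0.288058,0
0.289126,0
0.290194,0
0.291262,0
0.29233,0
0.293398,0
0.294466,0
0.295534,0
0.296602,0
0.29767,0
0.298738,0
0.299806,0
0.300874,0
0.301942,0
0.30301,0
0.304078,0
0.305146,0
0.306214,0
0.307282,0
0.30835,0
0.309417,0
0.310485,0
0.311553,0
0.312621,0
0.313689,0
0.314757,0
0.315825,0
0.316893,0
0.317961,0
0.319029,0
0.320097,0
0.321165,0
0.322233,0
0.323301,0
0.324369,0
0.325437,0
0.326505,0
0.327573,0
0.328641,0
0.329709,0
0.330777,0
0.331845,0
0.332913,0
0.333981,0
0.335049,0
0.336117,0
0.337184,0
0.338252,0
0.33932,0
0.340388,0
0.341456,0
0.342524,0
0.343592,0
0.34466,0
0.345728,0
0.346796,0
0.347864,0
0.348932,0
0.35,0
0.001,0
0.001129,0
0.001259,0
0.001388,0
0.001518,0
0.001647,0
0.001777,0
0.001906,0
0.002036,0
0.002165,0
0.002295,0
0.002424,0
0.002553,0
0.002683,0
0.002812,0
0.002942,0
0.003071,0
0.003201,0
0.00333,0
0.00346,0
0.003589,0
0.003718,0
0.003848,0
0.003977,0
0.004107,0
0.004236,0
0.004366,0
0.004495,0
0.004625,0
0.004754,0
0.004884,0
0.005013,0
0.005142,0
0.005272,0
0.005401,0
0.005531,0
0.00566,0
0.00579,0
0.005919,0
0.006049,0
0.006178,0
0.006308,0
0.006437,0
0.006566,0
0.006696,0
0.006825,0
0.006955,0
0.007084,0
0.007214,0
0.007343,0
0.007473,0
0.007602,0
0.007732,0
0.007861,0
0.00799,0
0.00812,0
0.008249,0
0.008379,0
0.008508,0
0.008638,0
0.008767,0
0.008897,0
0.009026,0
0.009155,0
0.009285,0
0.009414,0
0.009544,0
0.009673,0
0.009803,0
0.009932,0
0.010062,0
0.010191,0
0.010321,0
0.01045,0
0.010579,0
0.010709,0
0.010838,0
0.010968,0
0.011097,0
0.011227,0
0.011356,0
0.011486,0
0.011615,0
0.011745,0
0.011874,0
0.012003,0
0.012133,0
0.012262,0
0.012392,0
0.012521,0
0.012651,0
0.01278,0
0.01291,0
0.013039,0
0.013168,0
0.013298,0
0.013427,0
0.013557,0
0.013686,0
0.013816,0
0.013945,0
0.014075,0
0.014204,0
0.014334,0
0.014463,0
0.014592,0
0.014722,0
0.014851,0
0.014981,0
0.01511,0
0.01524,0
0.015369,0
0.015499,0
0.015628,0
0.015758,0
0.015887,0
0.016016,0
0.016146,0
0.016275,0
0.016405,0
0.016534,0
0.016664,0
0.016793,0
0.016923,0
0.017052,0
0.017182,0
0.017311,0
0.01744,0
0.01757,0
0.017699,0
0.017829,0
0.017958,0
0.018088,0
0.018217,0
0.018347,0
0.018476,0
0.018605,0
0.018735,0
0.018864,0
0.018994,0
0.019123,0
0.019253,0
0.019382,0
0.019512,0
0.019641,0
0.019771,0
0.0199,0
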