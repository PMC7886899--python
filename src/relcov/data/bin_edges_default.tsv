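edge
-0.025
-0.02
-0.015
-0.0125
-0.01
-0.008
-0.006
-0.005
-0.004
-0.003
-0.0025
-0.002
-0.0015
-0.001
-0.0005
0.0
0.0005
0.001
0.0015
0.002
0.0025
0.003
0.004
0.005
0.006
0.008
0.01
0.0125
0.015
0.0175
0.02
0.0225
0.025
0.03
0.035
0.04
0.045
0.05
0.065
0.08
0.1
0.12
0.14
0.1875
0.23
0.28125
0.33
0.375
0.42
0.46875
0.53125
0.6
0.75
0.9
1.1
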