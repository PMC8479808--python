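Z1 coarse-grained GAG elongation parameters
MASS
Z1 225.0

BOND
Z1-Z1  120.0  5.2
Z1-Cg  120.0  5.2
Os-Z1  120.0  2.8

ANGLE
Z1-Z1-Z1  100.0  160.0
Z1-Z1-Cg  100.0  160.0
Z1-Cg-H2  70.0  108.5
Z1-Cg-Cg  70.0  108.5
Z1-Cg-Os  60.0  110.0
Cg-Os-Z1  100.0  160.0
Os-Z1-Z1  100.0  160.0

DIHE
Z1-Z1-Z1-Z1  1  1.0  0.0  1.0
Z1-Z1-Z1-Cg  1  1.0  0.0  1.0
Z1-Z1-Cg-Cg  1  0.16  0.0  3.0
Z1-Cg-Cg-H1  1  0.16  0.0  3.0
Z1-Cg-Cg-H2  1  0.16  0.0  3.0
Z1-Z1-Cg-H2  1  0.16  0.0  3.0
Z1-Z1-Cg-Os  1  0.16  0.0  3.0
Z1-Cg-Cg-Ng  1  -1.3  0.0  1.0
Z1-Cg-Cg-Cg  1  -0.27  0.0  1.0
Z1-Cg-Os-Cg  1  -0.27  0.0  1.0
Cg-Cg-Os-Z1  1  0.16  0.0  3.0
Cg-Os-Z1-Z1  1  0.16  0.0  3.0
H1-Cg-Os-Z1  1  0.27  0.0  3.0
Z1-Cg-Cg-Os  1  0.16  0.0  3.0
Os-Z1-Z1-Z1  1  0.16  0.0  3.0

NONBON
  Z1  4.0  3.4

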