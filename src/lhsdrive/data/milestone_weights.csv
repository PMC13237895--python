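milestone,clinical,education,research,governance
K1,0.20,0.15,0.25,0.40
K2,0.10,0.25,0.50,0.15
K3,0.05,0.05,0.70,0.20
K4,0.45,0.20,0.25,0.10
K5,0.35,0.30,0.25,0.10
K6,0.25,0.15,0.20,0.40
K7,0.50,0.20,0.15,0.15
K8,0.30,0.20,0.15,0.35
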