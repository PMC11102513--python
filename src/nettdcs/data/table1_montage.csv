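electrode_label,anodal_current_uA,anodal_density_mA_cm2,cathodal_current_uA,cathodal_density_mA_cm2
P8,251,0.08,-251,-0.08
F4,-524,-0.17,524,0.17
C4,-353,-0.11,353,0.11
FP2,345,0.11,-345,-0.11
FPZ,2000,0.64,-2000,-0.64
Fp1,342,0.11,-342,-0.11
AF3,-1548,-0.49,1548,0.49
Fz,357,0.11,-357,-0.11
AF4,-1038,-0.33,1038,0.33
O1,246,0.08,-246,-0.08
F7,459,0.15,-459,-0.15
FC5,-537,-0.17,537,0.17
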