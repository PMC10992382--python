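species,197-2021,7002,RPE
xylose,0.41 ± 0.01,0.67 ± 0.03,0.50 ± 0.11
glycerol,0.18 ± 0.03,0.28 ± 0.06,0.46 ± 0.07
co2_uptake,–,0.05 ± 0.002,0.18 ± 0.04
lactate,0.57 ± 0.02,0.89 ± 0.03,1.01 ± 0.11
acetate,0.11 ± 0.01,0.11 ± 0.02,0.18 ± 0.02
ethanol,0.01 ± 0.002,0.06 ± 0.01,0.06 ± 0.01
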