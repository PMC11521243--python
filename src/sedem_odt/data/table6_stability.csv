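# Accelerated stability study (40 C / 75% RH) of the nine formulations: assay,
# dissolution and disintegration time at 0, 3 and 6 months (means +/- sd as
# published; assay n=3, dissolution n=6, disintegration n=3).
label,month,assay_pct,assay_sd,dissolution_pct,dissolution_sd,disintegration_s,disintegration_sd
F1,0,99.30,0.26,98.45,0.27,10,0.16
F1,3,99.21,0.74,99.00,0.08,11,0.01
F1,6,99.19,0.42,99.00,0.08,12,0.17
F2,0,99.12,0.41,98.88,0.24,12,0.10
F2,3,98.20,0.84,99.08,0.82,13,0.01
F2,6,98.10,0.44,98.90,0.05,14,0.07
F3,0,99.03,0.89,99.36,0.85,11,0.02
F3,3,98.02,0.44,98.34,0.25,12,0.10
F3,6,98.01,0.43,98.20,0.25,13,0.13
F4,0,98.48,0.56,99.66,0.69,13,0.01
F4,3,98.10,0.64,98.51,0.62,14,0.01
F4,6,98.02,0.22,97.01,0.22,15,0.02
F5,0,98.45,0.25,98.46,0.49,12,0.06
F5,3,98.10,0.38,98.66,0.01,13,0.02
F5,6,97.92,0.42,98.02,0.85,14,0.17
F6,0,99.63,0.18,99.36,0.89,12,0.05
F6,3,98.30,0.48,98.00,0.43,13,0.06
F6,6,98.01,0.53,97.02,0.25,14,0.12
F7,0,98.46,0.37,98.12,0.97,11,0.09
F7,3,98.01,0.82,98.50,0.75,12,0.02
F7,6,97.99,0.56,97.88,0.28,13,0.22
F8,0,99.62,0.25,99.36,0.49,13,0.01
F8,3,98.01,0.56,98.35,0.52,14,0.13
F8,6,98.01,0.43,97.48,0.10,15,0.24
F9,0,98.33,0.45,98.39,0.74,13,0.01
F9,3,99.01,0.72,99.00,0.12,14,0.01
F9,6,98.23,0.73,98.02,0.52,15,0.01
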