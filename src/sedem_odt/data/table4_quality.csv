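# Physicochemical quality attributes of the nine tablet batches (mean +/- sd
# where published). The F4 dissolution entry was published as "990.66", an
# obvious typographical slip for 99.66; the corrected value is carried here.
label,weight_mg,weight_sd,thickness_mm,thickness_sd,hardness_kg,hardness_sd,friability_pct,disintegration_s,dissolution_pct,dissolution_sd,assay_pct,assay_sd,wetting_s,wetting_sd
F1,219.9,2.231,4.29,0.06,3.09,0.08,0.56,11,98.00,1.17,99.30,0.92,9,2.32
F2,275.8,2.567,4.36,0.07,3.16,0.06,0.52,12,99.92,0.37,99.01,0.54,13,1.58
F3,240.9,2.560,4.75,0.04,3.10,0.09,0.54,10,98.65,0.42,98.68,0.57,12,3.56
F4,246.9,2.277,4.18,0.02,3.05,0.08,0.53,13,99.66,0.75,98.48,1.11,9,4.26
F5,265.3,1.593,4.59,0.01,3.17,0.05,0.51,12,99.23,0.47,98.84,0.28,8,3.18
F6,223.4,2.583,4.95,0.07,3.18,0.06,0.53,12,99.26,0.35,98.56,0.52,10,4.17
F7,230.7,2.922,4.62,0.04,3.12,0.07,0.55,11,98.06,0.39,98.39,0.09,8,1.55
F8,253.1,2.573,4.10,0.04,3.01,0.05,0.58,13,99.03,1.21,98.40,0.55,11,4.65
F9,281.6,2.927,4.81,0.06,3.21,0.05,0.57,13,98.36,0.45,99.00,0.91,10,5.12
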