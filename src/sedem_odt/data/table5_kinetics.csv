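# Published release-kinetics fits per formulation at pH 7.2: coefficient of
# determination and rate/shape constants for the four candidate models. Used as
# the model-selection fixture and as generator truth constants; the raw
# dissolution percentages behind them were published only graphically.
formulation,first_order_r2,first_order_k1,higuchi_r2,higuchi_kH,hixson_crowell_r2,hixson_crowell_kHC,weibull_r2,weibull_beta,weibull_alpha
F1,0.902,0.198,0.953,26.301,0.819,0.052,0.944,0.792,3.456
F2,0.812,0.163,0.940,24.559,0.740,0.043,0.876,0.748,3.748
F3,0.774,0.160,0.923,24.207,0.662,0.042,0.887,0.693,3.425
F4,0.764,0.152,0.925,23.755,0.659,0.041,0.879,0.691,3.553
F5,0.833,0.180,0.936,25.312,0.708,0.047,0.929,0.715,3.240
F6,0.891,0.171,0.972,24.940,0.810,0.045,0.941,0.776,3.806
F7,0.797,0.171,0.930,24.813,0.674,0.045,0.908,0.699,3.281
F8,0.781,0.157,0.929,24.054,0.671,0.042,0.892,0.695,3.487
F9,0.891,0.193,0.961,26.116,0.802,0.051,0.939,0.780,3.440
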