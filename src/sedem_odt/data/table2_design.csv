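# Central composite design and tablet compositions of the nine formulations.
# lud/ccs_pct_printed are the percent levels as published; *_pct_as_used are the
# levels implied by the published milligram entries (the source mixes precisions:
# F2 used the 4-decimal axial level 56.2426 while F5/F6/F7 used the display-
# truncated 5.82 / 47.75 / 0.171). mg entries and tablet weight are as published
# (3-decimal truncation of exact arithmetic on the as_used levels).
run,c1,c2,lud_pct_printed,ccs_pct_printed,lud_pct_as_used,ccs_pct_as_used,lud_mg,ccs_mg,aerosil_mg,talc_mg,aspartame_mg,mg_stearate_mg,api_mg,tablet_weight_mg
F1,-1,-1,49,1,49,1,107.692,2.197,0.307,5.186,2.197,2.197,100,219.780
F2,1.4142135623730951,0,56.242,3,56.2426,3,155.120,8.274,0.386,6.509,2.758,2.758,100,275.805
F3,-1,1,49,5,49,5,118.072,12.048,0.337,5.686,2.409,2.409,100,240.963
F4,0,0,52,3,52,3,128.395,7.407,0.345,5.827,2.469,2.469,100,246.913
F5,0,1.4142135623730951,52,5.82,52,5.82,138.004,15.445,0.371,6.263,2.653,2.653,100,265.392
F6,-1.4142135623730951,0,47.75,3,47.75,3,106.703,6.703,0.312,5.273,2.234,2.234,100,223.463
F7,0,-1.4142135623730951,52,0.171,52,0.171,120.012,0.394,0.323,5.446,2.307,2.307,100,230.792
F8,1,-1,55,1,55,1,139.240,2.531,0.354,5.974,2.531,2.531,100,253.164
F9,1,1,55,5,55,5,154.929,14.084,0.394,6.647,2.816,2.816,100,281.690
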