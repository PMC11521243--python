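# Classic 12-parameter SeDeM radius profiles of the API (flurbiprofen) and the
# direct-compression excipient (ludipress), with the published incidence means
# and indices (reliability factor f12 = 0.952).
label,Da,Dc,Ie,IC,Icd,IH,theta,t_flow,HR,H,Pf,Itheta,dimension,compressibility,flowability,lubricity_stability,lubricity_dosage,IP,IPP,IGC
flurbiprofen,4.80,6.20,3.92,4.52,0.56,6.55,3.49,4.50,6.00,5.70,9.99,0.49,5.50,3.00,4.85,5.85,5.24,0.42,4.73,4.50
ludipress,3.80,7.10,10.19,9.30,1.71,5.66,3.96,5.95,7.23,9.90,8.18,7.71,5.45,7.07,5.19,8.57,7.95,0.75,6.72,6.40
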