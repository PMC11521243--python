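# SeDeM-ODT 15-parameter radius profiles of the nine formulation blends (F1-F9)
# with the published incidence means and indices (reliability factor f15 = 0.950).
# Published disgregability incidences sit 0.05-0.09 below the arithmetic mean of
# their three member radii; they are carried here as printed, for reference only.
label,Da,Dc,Ie,IC,Icd,IH,theta,t_flow,HR,H,Pf,Itheta,effervescence,DCD,DSD,dimension,compressibility,flowability,lubricity_stability,lubricity_dosage,disgregability,IP,IPP,IGCB
F1,3.70,6.46,9.50,8.44,1.51,6.30,3.35,4.50,8.64,8.60,9.99,0.32,9.54,9.45,9.32,5.08,6.48,4.72,8.62,5.16,9.39,0.67,6.64,6.31
F2,3.40,5.10,8.16,6.66,1.49,6.38,3.49,5.67,6.60,8.46,9.99,0.34,9.56,9.32,9.27,4.25,5.44,5.18,7.53,5.17,9.30,0.73,6.26,5.95
F3,3.31,5.41,9.82,7.78,1.52,6.81,3.17,4.99,5.89,8.28,9.99,0.41,9.56,9.38,9.32,4.36,6.37,4.99,7.09,5.20,9.35,0.67,6.38,6.06
F4,3.30,5.00,8.58,6.80,1.52,6.07,2.98,4.83,5.88,8.28,9.99,0.44,9.60,9.27,9.45,4.15,5.63,4.63,7.08,5.22,9.36,0.67,6.13,5.83
F5,3.58,6.18,9.79,8.41,1.55,6.14,3.20,4.16,6.95,8.33,9.99,0.34,9.50,9.32,9.38,4.88,6.58,4.50,7.64,5.17,9.35,0.67,6.45,6.13
F6,3.50,5.50,8.65,7.27,1.56,5.16,3.20,4.66,7.43,8.42,9.98,0.45,9.48,9.32,9.32,4.50,5.83,4.34,7.93,5.22,9.32,0.67,6.26,5.95
F7,3.54,5.88,9.36,7.95,1.53,5.80,3.19,4.61,7.23,8.40,9.99,0.27,9.56,9.38,9.22,4.71,6.28,4.53,7.82,5.13,9.30,0.67,6.39,6.07
F8,3.50,5.50,8.65,7.27,1.55,5.98,2.76,4.54,7.70,8.31,9.99,0.30,9.53,9.27,9.32,4.50,5.82,4.43,8.01,5.15,9.30,0.67,6.28,5.96
F9,3.40,5.20,8.48,6.92,1.57,5.63,2.99,3.83,5.89,8.41,9.99,0.28,9.56,9.27,9.32,4.30,5.66,4.15,7.15,5.14,9.30,0.67,6.05,5.75
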