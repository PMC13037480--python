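species,P50,P50_ci95,WD,WD_ci95,psi_tlp,psi_tlp_ci95,SLA,SLA_ci95,C_std,C_std_ci95,SWC_br,SWC_br_ci95,RWC_tlp,RWC_tlp_ci95,g_min,g_min_ci95
Acacia nigrescens,-5.31,0.32,0.77,0.03,-1.85,0.09,95.90,6.70,5.71,1.16,1.14,0.12,0.94,0.05,4.51,0.82
Cassia abbreviata,-3.96,0.79,0.84,0.04,-2.05,0.44,97.0,14.2,1.58,0.44,0.98,0.09,0.85,0.03,5.16,2.60
Combretum apiculatum,-5.26,0.75,0.74,0.05,-1.79,0.05,78.80,4.09,4.59,0.45,1.08,0.09,0.87,0.02,4.99,2.88
Dichrostachys cinerea,-6.58,1.96,0.85,0.04,-2.99,0.49,50.50,1.69,3.30,1.08,1.17,0.11,0.71,0.05,9.79,1.21
Sclerocarya birrea,-1.55,0.14,0.65,0.08,-2.02,0.15,70.80,8.05,7.93,3.56,1.63,0.14,0.86,0.05,8.89,2.66
Terminalia sericea,-2.22,0.46,0.68,0.04,-1.40,0.10,66.70,7.35,18.46,5.93,1.48,0.22,0.90,0.03,5.03,2.16
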