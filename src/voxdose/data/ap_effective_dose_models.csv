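energy_MeV,ICRP-116,XGB-SA,MCNPX,OpenMC,OpenMC_uncertainty
0.01,0.0685,0.053404,0.0521,0.044117,3.38e-09
0.015,0.156,0.133008,,0.133593,5.03e-08
0.02,0.225,0.238327,0.247,0.17249,7.57e-08
0.03,0.312,0.349581,,0.275499,5.27e-08
0.04,0.35,0.389384,,0.30138,3.26e-08
0.05,0.369,0.403176,0.309,0.319378,2.79e-08
0.06,0.389,0.415689,,0.344054,2.97e-08
0.07,0.411,0.441238,,0.374955,3.11e-08
0.08,0.443,0.469633,,0.397938,3.74e-08
0.1,0.518,0.544638,0.478,0.478776,4.32e-08
0.15,0.747,0.792887,,0.711307,8.09e-08
0.2,1.0,1.031243,0.98,0.934966,1.19e-07
0.3,1.51,1.553238,,1.469746,1.98e-07
0.4,2.0,2.036597,,1.908442,1.96e-06
0.5,2.47,2.498128,2.44,2.345238,1.23e-06
0.511,2.52,2.542566,,2.399972,1.19e-06
0.6,2.91,2.920783,,2.776333,1.86e-06
0.662,3.17,3.200496,,3.145769,2.29e-06
0.8,3.73,3.78699,,3.519958,3.54e-06
1.0,4.49,4.541924,4.46,3.878794,5.15e-06
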