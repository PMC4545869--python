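probe_id,chromosome,gene,region,atopy_or,atopy_p,ige_or,ige_p,repl_or,repl_p
cg04983687,16,ZFPM1,Body,0.239,6.46e-09,0.158,3.54e-05,0.269,3.17e-06
cg09249800,1,ACOT7,Body,0.239,8.52e-09,0.141,1.13e-05,,
cg12819873,11,PRG2,5'UTR,0.065,1.38e-08,0.045,7.37e-05,0.140,2.36e-05
cg07908654,13,,,0.145,1.14e-07,0.103,8.44e-05,0.206,2.21e-04
cg06824199,1,KIAA0494,Body,0.107,6.28e-07,0.073,1.93e-04,0.118,2.96e-06
cg27469152,17,EPX,3'UTR,0.091,1.34e-06,0.025,6.06e-05,0.099,1.00e-05
cg27468224,4,,,0.123,1.62e-06,0.073,5.01e-04,0.262,1.89e-02
cg13233042,11,ATL3,Body,0.192,5.06e-06,0.105,1.82e-04,0.194,9.75e-05
cg13197551,20,LSM14B,3'UTR,0.160,5.67e-06,0.094,5.64e-04,0.312,1.04e-02
cg07765167,17,MRPL45,TSS1500,0.087,6.50e-06,0.043,5.96e-04,,
cg09332506,1,COPA,Body,0.123,7.77e-06,0.126,3.62e-03,0.196,8.72e-05
cg17041511,17,,,0.143,1.27e-05,0.075,8.14e-04,0.133,4.31e-05
cg24836822,7,KCNH2,Body,0.311,1.36e-05,0.225,7.13e-04,,
cg07970948,7,ZNF862,Body,0.243,1.38e-05,0.109,2.55e-04,0.313,1.61e-05
cg25854298,10,ASCC1,Body,0.221,3.69e-05,0.144,1.24e-03,0.149,1.21e-06
cg09635874,13,FARP1,Body,8.084,4.89e-05,2.591,2.44e-01,1.149,8.59e-01
cg04085542,5,FAM172A,Body;5'UTR,2.663,7.99e-05,1.250,5.48e-01,0.936,7.93e-01
cg03553407,4,ARHGAP10,Body,4.330,1.63e-04,2.411,1.92e-01,2.010,2.16e-01
cg12819826,19,PPAN;PPAN-P2RY11,TSS1500,0.213,2.45e-04,0.229,4.02e-02,1.788,2.87e-01
cg00854799,1,PEX10;RER1,3'UTR,4.209,2.48e-04,2.930,8.27e-02,1.464,5.18e-01
cg05652668,7,LUC7L2,1st exon;5'UTR,0.280,3.07e-04,0.517,2.39e-01,0.820,7.35e-01
cg17971837,22,PVALB,TSS1500,0.122,7.90e-04,0.102,4.11e-02,0.188,2.60e-02
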