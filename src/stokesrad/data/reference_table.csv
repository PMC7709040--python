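name,compound_class,mw,noc,r_s,r_e,d_s,d_e,d0,d0_source,d_c,dev_s,dev_e
xylose,sugar,150,14,3.09,3.39,7.94,7.24,7.50,experimental,6.78,0.44,-0.26
fructose,sugar,180,4,3.27,3.59,7.50,6.84,6.93,experimental,6.63,0.57,-0.09
galactose,sugar,180,6,3.27,3.62,7.50,6.77,6.90,derived,6.25,0.60,-0.13
glucose,sugar,180,10,3.28,3.69,7.48,6.65,6.79,experimental,5.77,0.69,-0.14
sucrose,sugar,342,15,4.03,4.84,6.09,5.07,5.23,experimental,4.93,0.86,-0.16
lactose,sugar,342,27,4.03,4.89,6.09,5.02,5.66,experimental,4.59,0.43,-0.64
trehalose,sugar,342,10,4.04,5.04,6.07,4.89,5.35,derived,4.70,0.72,-0.46
maltose,sugar,342,24,4.04,5.01,6.07,4.89,5.20,experimental,4.71,0.87,-0.31
alanine,amino acid,89,1,2.72,2.91,9.01,8.42,9.86,derived,9.21,-0.85,-1.44
proline,amino acid,115,2,2.97,3.18,8.25,7.71,8.39,derived,7.74,-0.14,-0.68
threonine,amino acid,119,2,2.95,3.24,8.31,7.56,8.64,derived,7.99,-0.33,-1.08
leucine,amino acid,131,7,3.20,3.51,7.66,6.75,7.65,derived,7.00,0.01,-0.90
aspartic acid,amino acid,133,2,2.92,3.19,8.39,7.70,8.55,derived,7.90,-0.16,-0.85
arginine,amino acid,174,2,3.41,4.10,7.19,5.98,7.45,derived,6.80,-0.26,-1.47
aspirin,drug,179,4,3.37,3.98,7.27,6.16,7.63,derived,6.98,-0.36,-1.47
salbutamol,drug,239,6,3.91,5.03,6.27,4.85,6.66,derived,6.01,-0.39,-1.81
loxoprofen,drug,246,8,3.89,5.17,6.30,4.77,6.56,derived,5.91,-0.26,-1.79
fast green fcf,drug,763,30,5.41,7.30,4.54,3.36,4.30,derived,3.65,0.24,-0.94
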