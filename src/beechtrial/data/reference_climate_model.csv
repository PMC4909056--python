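trait,n,alpha,se_alpha,beta,se_beta,sd_prov,sd_block,sd_resid,delta_i,lr,p
DBH,100,12.67,1.71,-0.18,0.32,1.84,0.21,1.30,1.59,0.41,0.52
Height,100,10.13,1.16,0.001,0.22,1.20,0.54,0.99,2.00,0.00,0.97
AGB,100,56.77,16.19,-2.01,3.04,17.45,0.00,11.91,1.47,0.53,0.47
BAI,100,25.19,7.78,-1.81,1.46,7.95,0.82,9.92,0.25,1.75,0.19
ABI,100,2.99,0.85,-0.11,0.16,0.92,0.00,0.63,1.47,0.53,0.47
P12,93,-2.15,0.16,0.01,0.03,0.11,0.17,0.28,1.93,0.07,0.80
P50,93,-3.13,0.12,0.03,0.02,0.08,0.14,0.22,0.43,1.57,0.21
P88,93,-4.06,0.16,0.04,0.03,0.14,0.07,0.29,0.20,1.80,0.18
KSemp,96,3.70,0.37,0.004,0.07,0.00,0.35,1.03,1.99,0.01,0.91
KStheo,98,3.24,0.51,0.25,0.09,0.10,0.00,1.69,4.26,6.26,0.01
KLemp,95,2.04,0.18,0.03,0.04,0.00,0.16,0.51,0.98,1.02,0.31
KLtheo,95,2.09,0.18,0.08,0.03,0.00,0.00,0.61,4.03,6.03,0.01
BA,100,2.56,0.15,-0.06,0.03,0.00,0.00,0.51,3.17,5.17,0.02
A_growth,98,16.42,1.20,0.19,0.22,0.00,0.00,4.07,1.29,0.71,0.40
lumen_fraction,98,12.40,1.03,0.48,0.19,0.53,0.00,3.09,3.72,5.72,0.02
VD,98,245.92,15.88,-0.27,2.97,14.11,0.00,31.90,1.99,0.01,0.92
D,98,23.99,0.67,0.43,0.13,0.00,0.00,2.28,7.45,9.45,0.002
D_h,98,32.05,1.07,0.33,0.20,0.58,0.00,3.18,0.84,2.84,0.09
A_leaf,100,23.98,2.08,-0.20,0.39,1.82,0.00,4.44,2.00,0.00,0.95
SLA,99,158.61,12.16,-0.72,2.28,0.00,8.79,39.16,1.89,0.11,0.74
huber,100,0.74,0.12,0.04,0.02,0.03,0.03,0.42,1.04,3.04,0.08
CN_ratio,100,24.80,0.59,0.25,0.11,0.35,0.00,1.73,3.12,5.12,0.02
d13C,100,-29.59,0.27,-0.11,0.05,0.12,0.00,0.86,2.63,4.63,0.03
Ca_mass,100,8.52,0.53,-0.06,0.10,0.00,0.15,1.79,1.66,0.34,0.56
K_mass,100,4.54,0.51,0.13,0.10,0.39,0.00,1.30,0.09,2.09,0.15
Mg_mass,100,1.62,0.12,-0.03,0.02,0.03,0.00,0.39,0.03,2.03,0.15
P_mass,100,1.21,0.05,0.001,0.01,0.00,0.00,0.18,1.98,0.02,0.89
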