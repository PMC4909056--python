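trait,cv_inter,cv_intra,vc_inter,vc_block,vc_intra,delta_i,lr,p
DBH,15.46,11.00,64.23,0.96,34.81,24.19,26.19,<0.001
Height,11.95,10.52,49.82,11.48,38.70,11.40,13.40,<0.001
AGB,36.98,25.44,66.73,0.00,33.27,32.88,34.88,<0.001
BAI,54.20,56.81,40.51,0.36,59.13,10.42,12.42,<0.001
ABI,37.00,25.44,66.79,0.00,33.21,32.89,34.89,<0.001
P12,7.88,14.51,8.38,25.20,66.43,1.41,0.59,0.22
P50,4.69,8.12,9.86,23.80,66.34,1.20,0.80,0.19
P88,4.87,7.20,8.38,25.20,66.43,2.18,4.18,0.02
KSemp,9.65,27.59,0.00,8.78,91.22,2.00,0.00,0.50
KStheo,15.69,35.52,6.93,0.00,93.07,0.57,1.43,0.12
KLemp,17.37,50.38,0.00,9.35,90.65,2.00,0.00,0.50
KLtheo,21.45,65.24,0.00,4.99,95.01,2.00,0.00,0.50
BA,7.63,19.81,0.99,0.00,99.01,1.96,0.04,0.42
A_growth,4.65,23.86,0.00,0.00,100.00,2.00,0.00,0.50
lumen_fraction,9.45,19.93,9.57,0.00,90.43,-0.56,2.56,0.05
VD,6.72,12.58,14.02,0.00,85.98,2.67,4.67,0.02
D,4.09,8.32,10.10,0.00,89.90,-0.51,2.51,0.06
D_h,3.75,9.14,5.31,0.00,94.69,1.20,0.80,0.19
A_leaf,9.07,18.08,12.09,0.00,87.91,0.77,2.77,0.05
SLA,7.28,23.88,0.00,3.86,96.14,2.00,0.00,0.50
huber,16.03,39.55,2.75,1.06,96.19,1.81,0.19,0.33
CN_ratio,3.02,6.56,9.77,0.00,90.23,0.37,2.37,0.06
d13C,1.16,2.73,6.48,0.00,93.52,0.88,1.12,0.14
Ca_mass,5.67,21.72,0.00,0.00,100.00,2.00,0.00,0.50
K_mass,11.43,23.55,9.85,0.00,90.15,0.20,2.20,0.07
Mg_mass,9.12,24.36,1.66,0.00,98.34,1.90,0.10,0.38
P_mass,3.81,13.12,0.00,0.00,100.00,2.00,0.00,0.50
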