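provenance,country,elevation_m,mat_c,map_mm,msp_mm,eq,gai,fai
BG,Bulgaria,900,15.3,945,214,32.12,0.67,6.09
CZ,Czech Republic,690,6.0,750,218,16.30,1.38,3.03
DE-BB,Germany,70,8.5,575,162,31.23,0.81,5.75
DE-SH,Germany,80,8.3,700,162,22.41,1.16,4.63
ES,Spain,950,9.9,860,170,33.79,0.66,9.16
RO,Romania,575,9.5,820,222,30.82,0.73,5.38
SE,Sweden,90,8.0,750,125,26.63,1.10,5.67
SK,Slovakia,200,9.0,670,211,27.99,0.79,4.59
SL,Slovenia,420,9.0,1050,286,19.67,1.37,3.68
UA,Ukraine,1150,3.4,1080,354,11.53,1.76,2.00
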