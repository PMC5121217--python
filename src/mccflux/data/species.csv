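name,n_C,n_H,n_O,molar_mass,cod_factor,pKa,carbon_number
ethanol,2,6,1,46.07,96.0,,2
acetate,2,4,2,60.05,64.0,4.76,2
propionate,3,6,2,74.08,112.0,4.87,3
n-butyrate,4,8,2,88.11,160.0,4.82,4
n-valerate,5,10,2,102.13,208.0,4.84,5
n-caproate,6,12,2,116.16,256.0,4.88,6
n-heptanoate,7,14,2,130.18,304.0,4.89,7
n-caprylate,8,16,2,144.21,352.0,4.89,8
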