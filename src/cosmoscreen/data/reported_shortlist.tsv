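# Literature-reported infinite-dilution activity coefficients of EPA in
# shortlisted ionic liquids at 298.15 K, with the capacities reported
# alongside them. Used as arithmetic inputs for the reciprocal
# capacity relation C_inf = 1/gamma_inf.
# ionic_liquid	gamma_inf	reported_capacity
[TMAm][SO4]	1.00e-11	9.97e10
[TMAm][Cl]	9.52e-10	1.05e9
[TMAm][Br]	3.61e-8	27677690
[EMPyrro][SO4]	4.40e-7	2273253
[EMPyrro][Cl]	1.68e-5	59473.56
[EMIM][SO4]	1.87e-5	53360.83
[MPPIP][SO4]	4.17e-5	23995.28
[EMPyr][SO4]	7.10e-5	14084.39
[BMPyrro][SO4]	9.03e-5	11073.19
[BPPIP][SO4]	2.13e-4	4689.32
[EMPyrro][Br]	2.41e-4	4147.65
[EMIM][Cl]	6.61e-4	1513.22
[TMAm][Propanoate]	6.97e-4	1434.47
[TMAm][NO3]	8.39e-4	1191.69
[EMPyrro][Propanoate]	8.67e-4	1153.16
[HMPyrro][SO4]	9.62e-4	1039.60
[MPPIP][Cl]	1.01e-3	991.30
[BMIM][SO4]	1.28e-3	781.77
[HPPIP][SO4]	1.28e-3	781.45
[BMPyr][SO4]	1.37e-3	727.47
[EMPyr][Cl]	1.74e-3	575.71
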