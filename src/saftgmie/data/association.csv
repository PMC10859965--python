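# saftgmie association parameter table, schema 1
# epsilon_HB/kB in kelvin, K_HB in angstrom^3; pairs not listed do not associate
group_k,site_a,group_l,site_b,epsilon_HB_over_kB,K_HB
cCOO,e1,CH3OH,H,1267.6,1095.9
cCOO,e1,CH2OH,H,1496.8,626.15
cCOO,e1,CHOH,H,1674.2,635.00
cCOO,e1,H2O,H,1385.6,576.40
CH3OH,H,CH3OH,e1,2062.1,106.57
CH3OH,e1,H2O,H,1993.5,104.11
CH3OH,H,H2O,e1,1993.5,104.11
CH2OH,H,CH2OH,e1,2097.9,62.309
CH2OH,H,CHOH,e1,2500.0,10.444
CH2OH,e1,CHOH,H,1464.1,591.55
CH2OH,e1,CH3COCH3,H,686.93,585.99
CH2OH,H,CH3COCH3,e1,1844.8,991.95
CH2OH,e1,H2O,H,2153.2,147.40
CH2OH,H,H2O,e1,621.68,425.00
CHOH,H,CHOH,e1,2480.6,8.4740
CHOH,e1,CH3COCH3,H,1186.9,731.08
CHOH,H,CH3COCH3,e1,1323.1,635.37
CHOH,e1,H2O,H,2140.9,19.478
CHOH,H,H2O,e1,2289.1,63.813
CH3COCH3,H,CH3COCH3,e1,980.20,2865.2
CH3COCH3,H,H2O,e1,1386.8,188.83
CH3COCH3,e1,H2O,H,1588.7,772.77
CH3COCH3,e2,H2O,H,417.24,1304.3
COO,e1,H2O,H,1245.8,454.98
aCH,e1,H2O,H,563.56,339.61
aCCH3,e1,H2O,H,563.56,339.61
aCCH2,e1,H2O,H,563.56,339.61
H2O,H,H2O,e1,1985.4,101.69
H2O,e1,CO2,e1,1398.1,91.419
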