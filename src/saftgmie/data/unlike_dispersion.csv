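# saftgmie unlike dispersion parameter table, schema 1
# epsilon/kB in kelvin; "CR" means the entry falls back to the combining rule
group_k,group_l,epsilon_over_kB,lambda_r
cCOO,cCOO,763.67,11.855
cCOO,cCH2,414.07,11.043
cCOO,cCH,519.28,8.2819
cCOO,CH3,411.61,33.394
cCOO,CH2,618.67,31.395
cCOO,CH,0.0000,CR
cCOO,CH3OH,434.59,CR
cCOO,CH2OH,500.14,CR
cCOO,CHOH,373.30,CR
cCOO,CH3COCH3,482.68,CR
cCOO,CH3CO,625.98,CR
cCOO,COO,756.57,9.9399
cCOO,aCH,543.64,17.749
cCOO,aCCH3,460.79,9.2834
cCOO,aCCH2,464.16,8.0000
cCOO,H2O,419.86,CR
cCOO,CO2,261.21,8.0000
cCH2,cCH2,477.36,20.386
cCH2,cCH,321.71,CR
cCH2,CH3,355.95,CR
cCH2,CH2,469.67,CR
cCH2,CH,570.45,CR
cCH2,CH3OH,361.42,CR
cCH2,CH2OH,424.64,CR
cCH2,CHOH,554.50,CR
cCH2,CH3COCH3,352.19,CR
cCH2,CH3CO,435.86,CR
cCH2,COO,498.60,CR
cCH2,aCH,393.05,15.377
cCH2,aCCH3,540.63,21.082
cCH2,aCCH2,439.78,9.9058
cCH2,H2O,350.99,28.000
cCH2,CO2,269.68,CR
cCH,cCH,699.92,8.0000
cCH,CH3,690.17,CR
cCH,CH2,522.57,CR
cCH,CH,0.0000,CR
cCH,CH3OH,345.00,CR
cCH,CH2OH,242.45,CR
cCH,CHOH,640.38,CR
cCH,CH3COCH3,409.28,CR
cCH,CH3CO,265.24,CR
cCH,COO,0.0000,CR
cCH,aCH,377.21,CR
cCH,aCCH3,792.29,CR
cCH,aCCH2,162.65,CR
cCH,H2O,377.16,22.265
cCH,CO2,294.99,CR
CH3,CH3,256.77,15.050
CH3,CH2,350.77,CR
CH3,CH,387.48,CR
CH3,CH3OH,275.76,15.537
CH3,CH2OH,333.20,CR
CH3,CHOH,479.38,CR
CH3,CH3COCH3,233.48,14.449
CH3,CH3CO,344.57,CR
CH3,COO,402.75,CR
CH3,aCH,305.81,CR
CH3,aCCH3,358.58,CR
CH3,aCCH2,396.91,CR
CH3,H2O,358.18,100.00
CH3,CO2,205.70,CR
CH2,CH2,473.39,19.871
CH2,CH,506.21,CR
CH2,CH3OH,341.41,17.050
CH2,CH2OH,423.17,CR
CH2,CHOH,517.64,CR
CH2,CH3COCH3,299.48,11.594
CH2,CH3CO,431.49,CR
CH2,COO,498.86,CR
CH2,aCH,415.64,CR
CH2,aCCH3,569.18,CR
CH2,aCCH2,454.16,CR
CH2,H2O,423.63,100.00
CH2,CO2,276.45,CR
CH,CH,95.621,8.0000
CH,CH3OH,CR,CR
CH,CH2OH,329.22,CR
CH,CHOH,0.0000,CR
CH,CH3COCH3,637.29,CR
CH,CH3CO,321.91,CR
CH,COO,353.65,CR
CH,aCH,441.43,CR
CH,aCCH3,769.36,8.0000
CH,aCCH2,65.410,CR
CH,H2O,275.75,CR
CH,CO2,CR,CR
CH3OH,CH3OH,307.69,19.235
CH3OH,CH2OH,CR,CR
CH3OH,CHOH,CR,CR
CH3OH,CH3COCH3,CR,CR
CH3OH,CH3CO,CR,CR
CH3OH,COO,CR,CR
CH3OH,aCH,330.19,CR
CH3OH,aCCH3,405.45,CR
CH3OH,aCCH2,CR,CR
CH3OH,H2O,278.45,CR
CH3OH,CO2,157.83,8.3462
CH2OH,CH2OH,407.22,22.699
CH2OH,CHOH,389.23,CR
CH2OH,CH3COCH3,338.47,CR
CH2OH,CH3CO,CR,CR
CH2OH,COO,CR,CR
CH2OH,aCH,386.05,CR
CH2OH,aCCH3,486.62,CR
CH2OH,aCCH2,434.37,CR
CH2OH,H2O,353.37,CR
CH2OH,CO2,312.30,CR
CHOH,CHOH,599.66,18.185
CHOH,CH3COCH3,340.81,CR
CHOH,CH3CO,CR,CR
CHOH,COO,CR,CR
CHOH,aCH,512.16,CR
CHOH,aCCH3,762.86,CR
CHOH,aCCH2,357.91,CR
CHOH,H2O,479.16,CR
CHOH,CO2,CR,CR
CH3COCH3,CH3COCH3,286.02,17.433
CH3COCH3,CH3CO,CR,CR
CH3COCH3,COO,547.44,CR
CH3COCH3,aCH,333.11,CR
CH3COCH3,aCCH3,479.55,35.957
CH3COCH3,aCCH2,394.83,CR
CH3COCH3,H2O,287.26,CR
CH3COCH3,CO2,CR,CR
CH3CO,CH3CO,525.22,19.050
CH3CO,COO,CR,CR
CH3CO,aCH,426.72,18.030
CH3CO,aCCH3,552.62,36.429
CH3CO,aCCH2,663.71,30.712
CH3CO,H2O,CR,CR
CH3CO,CO2,CR,CR
COO,COO,868.92,31.189
COO,aCH,534.18,22.088
COO,aCCH3,595.48,15.874
COO,aCCH2,265.62,9.3393
COO,H2O,396.81,15.140
COO,CO2,CR,CR
aCH,aCH,371.53,14.756
aCH,aCCH3,471.23,CR
aCH,aCCH2,416.69,CR
aCH,H2O,357.78,38.640
aCH,CO2,CR,CR
aCCH3,aCCH3,651.41,23.627
aCCH3,aCCH2,CR,CR
aCCH3,H2O,360.70,CR
aCCH3,CO2,CR,CR
aCCH2,aCCH2,591.56,8.5433
aCCH2,H2O,329.03,CR
aCCH2,CO2,CR,CR
H2O,H2O,266.68,17.020
H2O,CO2,226.38,CR
CO2,CO2,207.89,26.408
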