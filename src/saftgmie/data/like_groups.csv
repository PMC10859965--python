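# saftgmie like-group parameter table, schema 1
# units: sigma in angstrom, epsilon/kB in kelvin, mw in g/mol
name,nu_star,shape_factor,sigma,lambda_r,lambda_a,epsilon_over_kB,n_H,n_e1,n_e2,mw
cCOO,2,0.5787,3.2787,11.855,6.0000,763.67,0,2,0,44.009
cCH2,1,0.2475,4.7852,20.386,6.0000,477.36,0,0,0,14.027
cCH,1,0.0961,5.4116,8.0000,6.0000,699.92,0,0,0,13.019
CH3,1,0.5726,4.0772,15.050,6.0000,256.77,0,0,0,15.035
CH2,1,0.2293,4.8801,19.871,6.0000,473.39,0,0,0,14.027
CH,1,0.0721,5.2950,8.0000,6.0000,95.621,0,0,0,13.019
CH3OH,2,0.8352,3.2462,19.235,6.0000,307.69,1,2,0,32.042
CH2OH,2,0.5854,3.4054,22.699,6.0000,407.22,1,2,0,31.034
CHOH,2,0.1896,4.5381,18.185,6.0000,599.66,1,2,0,30.026
CH3COCH3,3,0.7214,3.5981,17.433,6.0000,286.02,1,1,1,58.080
CH3CO,2,0.5469,3.9112,19.050,6.0000,525.22,0,2,0,43.045
COO,1,0.6526,3.9939,31.189,6.0000,868.92,0,2,0,44.009
aCH,1,0.3218,4.0578,14.756,6.0000,371.53,0,1,0,13.019
aCCH3,1,0.3166,5.4874,23.627,6.0000,651.41,0,1,0,27.046
aCCH2,1,0.2086,5.2648,8.5433,6.0000,591.56,0,1,0,26.038
H2O,1,1.0000,3.0063,17.020,6.0000,266.68,2,2,0,18.015
CO2,2,0.8468,3.0500,26.408,5.0550,207.89,0,1,1,44.009
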