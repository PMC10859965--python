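# saftgmie fusion-property table, schema 1
# delta_h_fus in kJ/mol at 1 bar, T_fus in K; empty delta_h_fus means not measured
molecule,delta_h_fus,T_fus
oxolan-2-one,9.57,229.78
oxepan-2-one,13.82,272.13
5-methyloxolan-2-one,7.1,238.34
cyclohexane,2.63,279.75
methanol,3.21,175.49
ethanol,5.02,158.65
propan-1-ol,5.20,147.05
butan-1-ol,9.28,183.35
pentan-1-ol,9.83,194.25
acetone,5.69,178.35
butan-2-one,8.44,186.48
pentan-2-one,10.63,196.31
hexan-2-one,14.9,216.25
methyl acetate,7.97,175
ethyl acetate,10.48,189.55
propyl acetate,11.2,178
butyl acetate,14.4,199.7
diethylbutanedioate,,252.55
benzene,9.82,278.33
toluene,6.6,178.2
ethylbenzene,9.2,178.2
water,6.0,273.15
carbon dioxide,7.9,216.6
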