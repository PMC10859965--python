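# saftgmie molecule definitions, schema 1
# each molecule is a named multiset of group counts; cas is optional
oxolan-2-one:
  cas: 96-48-0
  groups: {cCOO: 1, cCH2: 3}
oxan-2-one:
  cas: 542-28-9
  groups: {cCOO: 1, cCH2: 4}
oxepan-2-one:
  cas: 502-44-3
  groups: {cCOO: 1, cCH2: 5}
oxocan-2-one:
  cas: 539-87-7
  groups: {cCOO: 1, cCH2: 6}
oxonan-2-one:
  cas: 5698-29-3
  groups: {cCOO: 1, cCH2: 7}
oxecan-2-one:
  cas: 6008-27-1
  groups: {cCOO: 1, cCH2: 8}
5-methyloxolan-2-one:
  cas: 108-29-2
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH3: 1}
5-ethyloxolan-2-one:
  cas: 695-06-7
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH2: 1, CH3: 1}
5-propyloxolan-2-one:
  cas: 105-21-5
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH2: 2, CH3: 1}
5-butyloxolan-2-one:
  cas: 104-50-7
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH2: 3, CH3: 1}
5-pentyloxolan-2-one:
  cas: 104-61-0
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH2: 4, CH3: 1}
5-hexyloxolan-2-one:
  cas: 706-14-9
  groups: {cCOO: 1, cCH2: 2, cCH: 1, CH2: 5, CH3: 1}
6-methyloxan-2-one:
  cas: 823-22-3
  groups: {cCOO: 1, cCH2: 3, cCH: 1, CH3: 1}
6-ethyloxan-2-one:
  cas: 3301-90-4
  groups: {cCOO: 1, cCH2: 3, cCH: 1, CH2: 1, CH3: 1}
6-propyloxan-2-one:
  cas: 698-76-0
  groups: {cCOO: 1, cCH2: 3, cCH: 1, CH2: 2, CH3: 1}
6-butyloxan-2-one:
  cas: 3301-94-8
  groups: {cCOO: 1, cCH2: 3, cCH: 1, CH2: 3, CH3: 1}
6-pentyloxan-2-one:
  cas: 705-86-2
  groups: {cCOO: 1, cCH2: 3, cCH: 1, CH2: 4, CH3: 1}
cyclohexane:
  cas: 110-82-7
  groups: {cCH2: 6}
methanol:
  cas: 67-56-1
  groups: {CH3OH: 1}
1,4-butanediol:
  cas: 110-63-4
  groups: {CH2: 2, CH2OH: 2}
2-methyl-1-propanol:
  cas: 78-83-1
  groups: {CH3: 2, CH: 1, CH2OH: 1}
3-methyl-1-butanol:
  cas: 123-51-3
  groups: {CH3: 2, CH2: 1, CH: 1, CH2OH: 1}
acetone:
  cas: 67-64-1
  groups: {CH3COCH3: 1}
methyl acetate:
  cas: 79-20-9
  groups: {COO: 1, CH3: 2}
ethyl acetate:
  cas: 141-78-6
  groups: {COO: 1, CH2: 1, CH3: 2}
diethylbutanedioate:
  cas: 123-25-1
  groups: {COO: 2, CH2: 4, CH3: 2}
benzene:
  cas: 71-43-2
  groups: {aCH: 6}
toluene:
  cas: 108-88-3
  groups: {aCH: 5, aCCH3: 1}
ethylbenzene:
  cas: 100-41-4
  groups: {aCH: 5, aCCH2: 1, CH3: 1}
water:
  cas: 7732-18-5
  groups: {H2O: 1}
carbon dioxide:
  cas: 124-38-9
  groups: {CO2: 1}
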