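# Naphthalene fluorescence titration against RHCC-NT
# emission at 350 nm, excitation at 275 nm
# unit: uM
# ligand_total: 4
# temperature_K: 293.15
protein_conc,intensity
0,708292
0.12,709824
0.24,730572
0.48,733694
0.96,780644
1.9,906120
3.8,1003650
7.7,1177910
15.4,1420260
30.75,1845910
61.5,1873130
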