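# Absolute hardness (eV) from Parr & Pearson, J. Am. Chem. Soc. 105 (1983) 7512
# (as tabulated in Pearson, Inorg. Chem. 27 (1988) 734); electronegativity on
# the Pauling scale. Group G of the softness definition.
element,hardness_ev,electronegativity
C,5.00,2.55
N,7.23,3.04
O,6.08,3.44
S,4.14,2.58
F,7.01,3.98
CL,4.68,3.16
BR,4.22,2.96
I,3.69,2.66
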