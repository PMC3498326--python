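index,zinc,pm_per_mass,rot_bonds,phob_phil,label,subgroup
1,21789,0.053,2,2.33,ligand,0
2,330141,0.071,0,6,ligand,0
3,3801154,0.038,3,6,ligand,0
4,3814483,0.011,2,2,ligand,0
5,3814484,0.049,1,6,ligand,0
6,3814485,0.051,1,6,ligand,0
7,33882,0.052,2,6,ligand,0
8,52627624,0.078,5,12,ligand,0
9,22831,0.049,0,3,decoy,1
10,366295,0.050,3,2,decoy,1
11,366296,0.044,3,2,decoy,1
12,370041,0.033,3,2.5,decoy,1
13,370042,0.036,3,2.4,decoy,1
14,370157,0.015,2,4.5,decoy,1
15,370162,0.029,2,4.5,decoy,1
16,402870,0.055,2,3,decoy,1
17,438536,0.032,2,3,decoy,1
18,1833085,0.010,1,3.67,decoy,1
19,2519115,0.050,2,4.5,decoy,2
20,2990158,0.010,1,3.33,decoy,2
21,3836392,0.000,2,3,decoy,2
22,3871444,0.041,3,4.5,decoy,2
23,3973802,0.000,2,3,decoy,2
24,3995296,0.040,3,2,decoy,2
25,4000727,0.030,3,2,decoy,2
26,4404113,0.036,1,2.33,decoy,2
27,4443675,0.039,3,4.5,decoy,2
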