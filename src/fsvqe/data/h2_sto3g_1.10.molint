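format molint-1
molecule H2
basis_label STO-3G
geometry_id 1.100
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.48107019172999993
hf_energy -1.0365388750183113
one_body:
0 0 -1.0633903726398248
1 1 -1.0633903726398248
2 2 -0.6147527176817904
3 3 -0.6147527176817904
two_body:
0 0 0 0 0.6091716785313385
0 0 2 2 0.20322222662295159
0 1 0 1 0.6091716785313385
0 1 2 3 0.20322222662295159
0 2 0 2 0.6073354277148839
0 2 2 0 0.20322222662295164
0 3 0 3 0.6073354277148839
0 3 2 1 0.20322222662295164
1 1 1 1 0.6091716785313385
1 1 3 3 0.20322222662295159
1 2 1 2 0.6073354277148839
1 3 1 3 0.6073354277148839
1 3 3 1 0.20322222662295164
2 2 2 2 0.637479877148669
2 3 2 3 0.637479877148669
3 3 3 3 0.637479877148669
mo_coefficients:
-0.5893402909631084 -0.9445624413895531
-0.5893402909631081 0.9445624413895531
overlap:
1.0 0.4395864093710062
0.4395864093710062 1.0
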