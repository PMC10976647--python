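format molint-1
molecule H2
basis_label STO-3G
geometry_id 1.500
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.3527848072686667
hf_energy -0.9108735545799623
one_body:
0 0 -0.90818087245276
1 1 -0.90818087245276
2 2 -0.6653369357674778
3 3 -0.6653369357674778
two_body:
0 0 0 0 0.5527033830568909
0 0 2 2 0.22953593606280764
0 1 0 1 0.5527033830568909
0 1 2 3 0.22953593606280764
0 2 0 2 0.5596841556081746
0 2 2 0 0.2295359360628076
0 3 0 3 0.5596841556081746
0 3 2 1 0.2295359360628076
1 1 1 1 0.5527033830568909
1 1 3 3 0.22953593606280764
1 2 1 2 0.5596841556081746
1 3 1 3 0.5596841556081746
1 3 3 1 0.2295359360628076
2 2 2 2 0.5834207611980448
2 3 2 3 0.5834207611980448
3 3 3 3 0.5834207611980448
mo_coefficients:
-0.6307456687378199 -0.8202158538846851
-0.6307456687378199 0.8202158538846851
overlap:
1.0 0.25678633631925724
0.25678633631925724 1.0
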