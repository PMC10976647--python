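format molint-1
molecule H2
basis_label STO-3G
geometry_id 0.500
n_spin_orbitals 4
n_electrons 2
e_nuclear 1.058354421806
hf_energy -1.04299627455446
one_body:
0 0 -1.4105283677069123
1 1 -1.4105283677069123
2 2 -0.2569357824168738
3 3 -0.2569357824168738
two_body:
0 0 0 0 0.7197060390533649
0 0 2 2 0.16887022769048082
0 1 0 1 0.7197060390533649
0 1 2 3 0.16887022769048082
0 2 0 2 0.707239841541527
0 2 2 0 0.16887022769048082
0 3 0 3 0.707239841541527
0 3 2 1 0.16887022769048082
1 1 1 1 0.7197060390533649
1 1 3 3 0.16887022769048082
1 2 1 2 0.707239841541527
1 3 1 3 0.707239841541527
1 3 3 1 0.16887022769048082
2 2 2 2 0.7448393703665723
2 3 2 3 0.7448393703665723
3 3 3 3 0.7448393703665723
mo_coefficients:
-0.5249046467937994 -1.6427387333685064
-0.5249046467937998 1.6427387333685062
overlap:
1.0 0.814718093961716
0.814718093961716 1.0
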