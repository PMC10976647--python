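format molint-1
molecule H2
basis_label STO-3G
geometry_id 0.650
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.8141187860046153
hf_energy -1.1129965456723883
one_body:
0 0 -1.309509868451424
1 1 -1.309509868451424
2 2 -0.4100263808289929
3 3 -0.4100263808289929
two_body:
0 0 0 0 0.6919044052258445
0 0 2 2 0.17631845161130574
0 1 0 1 0.6919044052258445
0 1 2 3 0.17631845161130574
0 2 0 2 0.6796839139266886
0 2 2 0 0.17631845161130574
0 3 0 3 0.6796839139266886
0 3 2 1 0.17631845161130574
1 1 1 1 0.6919044052258445
1 1 3 3 0.17631845161130574
1 2 1 2 0.6796839139266886
1 3 1 3 0.6796839139266886
1 3 3 1 0.17631845161130574
2 2 2 2 0.7146711110340838
2 3 2 3 0.7146711110340838
3 3 3 3 0.7146711110340838
mo_coefficients:
-0.5393427614697563 -1.3335921824970043
-0.5393427614697566 1.3335921824970043
overlap:
1.0 0.7188591701989538
0.7188591701989538 1.0
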