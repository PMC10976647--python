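format molint-1
molecule H2
basis_label STO-3G
geometry_id 1.750
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.30238697765885714
hf_energy -0.8413485984399457
one_body:
0 0 -0.8357918583966338
1 1 -0.8357918583966338
2 2 -0.6723882711360235
3 3 -0.6723882711360235
two_body:
0 0 0 0 0.5278481406944646
0 0 2 2 0.24507502046622123
0 1 0 1 0.5278481406944646
0 1 2 3 0.24507502046622123
0 2 0 2 0.5371760266697381
0 2 2 0 0.2450750204662212
0 3 0 3 0.5371760266697381
0 3 2 1 0.2450750204662212
1 1 1 1 0.5278481406944646
1 1 3 3 0.24507502046622123
1 2 1 2 0.5371760266697381
1 3 1 3 0.5371760266697381
1 3 3 1 0.2450750204662212
2 2 2 2 0.556603172792628
2 3 2 3 0.556603172792628
3 3 3 3 0.556603172792628
mo_coefficients:
-0.6517011799681934 -0.7795682201008102
-0.6517011799681934 0.7795682201008103
overlap:
1.0 0.17726163056800748
0.17726163056800748 1.0
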