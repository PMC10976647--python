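format molint-1
molecule H2
basis_label STO-3G
geometry_id 0.900
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.5879746787811111
hf_energy -1.0919140410133894
one_body:
0 0 -1.1622206874578707
1 1 -1.1622206874578707
2 2 -0.5551123198313949
3 3 -0.5551123198313949
two_body:
0 0 0 0 0.6445526551212406
0 0 2 2 0.19057169376102526
0 1 0 1 0.6445526551212406
0 1 2 3 0.19057169376102526
0 2 0 2 0.6370806298904415
0 2 2 0 0.19057169376102537
0 3 0 3 0.6370806298904415
0 3 2 1 0.19057169376102537
1 1 1 1 0.6445526551212406
1 1 3 3 0.19057169376102526
1 2 1 2 0.6370806298904415
1 3 1 3 0.6370806298904415
1 3 3 1 0.19057169376102537
2 2 2 2 0.6694850379272905
2 3 2 3 0.6694850379272905
3 3 3 3 0.6694850379272905
mo_coefficients:
-0.5666495657486533 -1.062612748825131
-0.5666495657486533 1.062612748825131
overlap:
1.0 0.5571874100728993
0.5571874100728993 1.0
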