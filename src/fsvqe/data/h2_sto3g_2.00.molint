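format molint-1
molecule H2
basis_label STO-3G
geometry_id 2.000
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.2645886054515
hf_energy -0.7837926542641455
one_body:
0 0 -0.7789220360689513
1 1 -0.7789220360689513
2 2 -0.6702666718275385
3 3 -0.6702666718275385
two_body:
0 0 0 0 0.5094628124222572
0 0 2 2 0.25913847488445724
0 1 0 1 0.5094628124222572
0 1 2 3 0.25913847488445724
0 2 0 2 0.5192012581254143
0 2 2 0 0.2591384748844573
0 3 0 3 0.5192012581254143
0 3 2 1 0.2591384748844573
1 1 1 1 0.5094628124222572
1 1 3 3 0.25913847488445724
1 2 1 2 0.5192012581254143
1 3 1 3 0.5192012581254143
1 3 3 1 0.2591384748844573
2 2 2 2 0.5346641195242764
2 3 2 3 0.5346641195242764
3 3 3 3 0.5346641195242764
mo_coefficients:
-0.6683869232339311 -0.7534430379286695
-0.668386923233931 0.7534430379286695
overlap:
1.0 0.11921652907137761
0.11921652907137761 1.0
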