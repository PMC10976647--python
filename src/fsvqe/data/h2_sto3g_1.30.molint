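format molint-1
molecule H2
basis_label STO-3G
geometry_id 1.300
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.40705939300230765
hf_energy -0.9731106157642337
one_body:
0 0 -0.9792234912222932
1 1 -0.9792234912222932
2 2 -0.6482421177160755
3 3 -0.6482421177160755
two_body:
0 0 0 0 0.5782769736780453
0 0 2 2 0.21641745962651454
0 1 0 1 0.5782769736780453
0 1 2 3 0.21641745962651454
0 2 0 2 0.5815867347973783
0 2 2 0 0.21641745962651454
0 3 0 3 0.5815867347973783
0 3 2 1 0.21641745962651454
1 1 1 1 0.5782769736780453
1 1 3 3 0.21641745962651454
1 2 1 2 0.5815867347973783
1 3 1 3 0.5815867347973783
1 3 3 1 0.21641745962651454
2 2 2 2 0.6087456384707882
2 3 2 3 0.6087456384707882
3 3 3 3 0.6087456384707882
mo_coefficients:
-0.6110602835614242 -0.8697728778076028
-0.6110602835614243 0.8697728778076027
overlap:
1.0 0.339065712438453
0.339065712438453 1.0
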