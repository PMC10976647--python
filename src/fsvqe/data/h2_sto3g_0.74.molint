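format molint-1
molecule H2
basis_label STO-3G
geometry_id 0.740
n_spin_orbitals 4
n_electrons 2
e_nuclear 0.7151043390581081
hf_energy -1.1167593073951996
one_body:
0 0 -1.2533097866316085
1 1 -1.2533097866316085
2 2 -0.4750688487871996
3 3 -0.4750688487871996
two_body:
0 0 0 0 0.6747559268099096
0 0 2 2 0.18121046201653138
0 1 0 1 0.6747559268099096
0 1 2 3 0.18121046201653138
0 2 0 2 0.6637114013466757
0 2 2 0 0.18121046201653135
0 3 0 3 0.6637114013466757
0 3 2 1 0.18121046201653135
1 1 1 1 0.6747559268099096
1 1 3 3 0.18121046201653138
1 2 1 2 0.6637114013466757
1 3 1 3 0.6637114013466757
1 3 3 1 0.18121046201653135
2 2 2 2 0.6976515044860735
2 3 2 3 0.6976515044860735
3 3 3 3 0.6976515044860735
mo_coefficients:
-0.5488422750912693 -1.2124519201518076
-0.5488422750912695 1.2124519201518076
overlap:
1.0 0.6598731217571141
0.6598731217571141 1.0
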