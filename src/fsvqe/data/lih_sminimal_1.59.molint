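format molint-1
molecule LiH
basis_label s-minimal
geometry_id 1.595
n_spin_orbitals 6
n_electrons 4
e_nuclear 0.9953176380620689
hf_energy -7.804242631939056
one_body:
0 0 -4.729388751530836
0 2 -0.13688638101095715
0 4 0.13421744248827747
1 1 -4.729388751530836
1 3 -0.13688638101095715
1 5 0.13421744248827747
2 2 -1.4447926637612436
2 4 -0.09385372309340939
3 3 -1.4447926637612436
3 5 -0.09385372309340939
4 4 -1.1256624614341988
5 5 -1.1256624614341988
two_body:
0 0 0 0 1.6598931385579134
0 0 0 2 0.13592135177887082
0 0 0 4 -0.12282756154325204
0 0 2 2 0.016965746428627304
0 0 2 4 -0.01514368508195739
0 0 4 4 0.014568370911398124
0 1 0 1 1.6598931385579134
0 1 0 3 0.13592135177887082
0 1 0 5 -0.12282756154325204
0 1 2 1 0.13592135177887082
0 1 2 3 0.016965746428627304
0 1 2 5 -0.01514368508195739
0 1 4 1 -0.12282756154325199
0 1 4 3 -0.015143685081957386
0 1 4 5 0.014568370911398124
0 2 0 2 0.3664753411370507
0 2 0 4 -0.03834537208781729
0 2 2 0 0.016965746428627308
0 2 2 2 0.0009650292320843262
0 2 2 4 -0.006140579678554086
0 2 4 0 -0.015143685081957384
0 2 4 2 -0.008765230311856076
0 2 4 4 -0.0011122298800049389
0 3 0 3 0.3664753411370507
0 3 0 5 -0.03834537208781729
0 3 2 1 0.016965746428627308
0 3 2 3 0.0009650292320843262
0 3 2 5 -0.006140579678554086
0 3 4 1 -0.015143685081957384
0 3 4 3 -0.008765230311856076
0 3 4 5 -0.0011122298800049389
0 4 0 4 0.3569980847426489
0 4 2 2 -0.006140579678554081
0 4 2 4 0.0027706627511005968
0 4 4 0 0.014568370911398124
0 4 4 2 -0.0011122298800049458
0 4 4 4 -0.005640626618967619
0 5 0 5 0.3569980847426489
0 5 2 1 -0.015143685081957388
0 5 2 3 -0.006140579678554081
0 5 2 5 0.0027706627511005968
0 5 4 1 0.014568370911398124
0 5 4 3 -0.0011122298800049458
0 5 4 5 -0.005640626618967619
1 1 1 1 1.6598931385579134
1 1 1 3 0.13592135177887082
1 1 1 5 -0.12282756154325204
1 1 3 3 0.016965746428627304
1 1 3 5 -0.01514368508195739
1 1 5 5 0.014568370911398124
1 2 1 2 0.3664753411370507
1 2 1 4 -0.03834537208781729
1 2 3 2 0.0009650292320843262
1 2 3 4 -0.006140579678554086
1 2 5 2 -0.008765230311856076
1 2 5 4 -0.0011122298800049389
1 3 1 3 0.3664753411370507
1 3 1 5 -0.03834537208781729
1 3 3 1 0.016965746428627308
1 3 3 3 0.0009650292320843262
1 3 3 5 -0.006140579678554086
1 3 5 1 -0.015143685081957384
1 3 5 3 -0.008765230311856076
1 3 5 5 -0.0011122298800049389
1 4 1 4 0.3569980847426489
1 4 3 2 -0.006140579678554081
1 4 3 4 0.0027706627511005968
1 4 5 2 -0.0011122298800049458
1 4 5 4 -0.005640626618967619
1 5 1 5 0.3569980847426489
1 5 3 3 -0.006140579678554081
1 5 3 5 0.0027706627511005968
1 5 5 1 0.014568370911398124
1 5 5 3 -0.0011122298800049458
1 5 5 5 -0.005640626618967619
2 2 2 2 0.4569395503340321
2 2 2 4 0.1554007821870779
2 2 4 4 0.14401146235885595
2 3 2 3 0.4569395503340321
2 3 2 5 0.1554007821870779
2 3 4 3 0.15540078218707784
2 3 4 5 0.14401146235885595
2 4 2 4 0.3862337940386547
2 4 4 2 0.14401146235885592
2 4 4 4 0.10226423341861167
2 5 2 5 0.3862337940386547
2 5 4 3 0.14401146235885592
2 5 4 5 0.10226423341861167
3 3 3 3 0.4569395503340321
3 3 3 5 0.1554007821870779
3 3 5 5 0.14401146235885595
3 4 3 4 0.3862337940386547
3 4 5 4 0.10226423341861167
3 5 3 5 0.3862337940386547
3 5 5 3 0.14401146235885592
3 5 5 5 0.10226423341861167
4 4 4 4 0.3561853986656033
4 5 4 5 0.3561853986656033
5 5 5 5 0.3561853986656033
mo_coefficients:
-0.9917166749061903 -0.2035871284426779 0.1945913443222371
-0.03220180097197342 0.5563424475803919 -0.9720293521312613
-0.00037456159368799176 0.6570730216119134 0.8694947900973942
overlap:
1.0 0.24113665118392041 0.06723063514443245
0.24113665118392041 1.0000000000000002 0.396519970772763
0.06723063514443245 0.39651997077276296 1.0
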