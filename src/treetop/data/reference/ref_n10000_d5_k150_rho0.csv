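max_score
3.303030303
2.696969697
4.343434343
1.575757576
2.191919192
2.626262626
2.858585859
3.01010101
1.919191919
1.808080808
3.242424242
2.898989899
4.202020202
2.292929293
1.747474747
2.95959596
1.878787879
2.939393939
2.070707071
1.919191919
2.04040404
3.848484848
2.161616162
2.313131313
2.111111111
2.555555556
2.262626263
2.04040404
2.333333333
3.242424242
1.616161616
2.292929293
2.676767677
2.242424242
1.949494949
2.515151515
4.03030303
3.929292929
2.636363636
4.111111111
2.323232323
2.919191919
2.808080808
2.505050505
2.858585859
2.494949495
3.535353535
3.131313131
1.939393939
2.727272727
2.171717172
2.545454545
1.868686869
2.080808081
2.939393939
3.818181818
4.151515152
3.272727273
2.555555556
2.676767677
2.646464646
2.95959596
1.686868687
3.161616162
3.292929293
3.505050505
2.838383838
3.363636364
3
2.464646465
4.121212121
2.363636364
3.404040404
2.383838384
3.050505051
2.909090909
3.111111111
2.575757576
2.292929293
2.777777778
3.070707071
2.313131313
3.070707071
2.050505051
1.939393939
2.545454545
2.292929293
3.03030303
2.505050505
2.444444444
2
2.676767677
3.616161616
1.787878788
2.808080808
2.505050505
2.686868687
2.111111111
1.797979798
3.707070707
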